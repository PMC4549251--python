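"""Infinium-450K-style differential methylation analysis.

Beta values from methylated/unmethylated intensities, detection-p quality
control, a paired Wilcoxon signed-rank test for global methylation shifts,
per-site hyper/hypo classification by log2 fold change (> 1 in magnitude),
CpG island detection with shore/shelf/open-sea annotation, functional-region
annotation, and the summary tables (category counts and percentages, gene
sets that are hyper- and/or hypomethylated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet

logger = logging.getLogger(__name__)

FUNCTIONAL_PRECEDENCE = ["TSS200", "TSS1500", "5'UTR", "1stExon", "gene body", "3'UTR"]
PROMOTER_CATEGORIES = {"TSS200", "TSS1500"}


def beta_values(M, U):
    """Methylation beta = M / (M + U), elementwise.

    Zero total intensity yields NaN (probe flagged missing) rather than an
    error, so array-wide computation survives failed probes.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if (M < 0).any() or (U < 0).any():
        raise ValueError("negative intensity")
    total = M + U
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, M / np.where(total > 0, total, 1.0), np.nan)
    return beta


def qc_filter(
    beta: pd.DataFrame,
    detection_p: pd.DataFrame,
    p_threshold: float = 0.05,
    min_sample_coverage: float = 0.95,
) -> tuple[pd.DataFrame, dict]:
    """Mask failed measures and drop low-coverage samples.

    Probe x sample measures with detection p > p_threshold become NaN; any
    sample whose fraction of passing probes falls below min_sample_coverage
    is removed entirely.  Returns (filtered beta, ledger) where the ledger
    records masked-measure counts and removed samples.
    """
    if beta.shape != detection_p.shape:
        raise ValueError("beta and detection_p must align")
    failed = detection_p > p_threshold
    out = beta.mask(failed)
    pass_frac = 1.0 - failed.mean(axis=0)
    removed = list(pass_frac.index[pass_frac < min_sample_coverage])
    out = out.drop(columns=removed)
    if out.shape[1] == 0:
        raise ValueError("all samples removed by QC")
    ledger = {
        "masked_measures": int(failed.to_numpy().sum()),
        "removed_samples": removed,
        "sample_pass_fraction": pass_frac.to_dict(),
    }
    return out, ledger


def _signed_rank_statistic(diff: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of midranks of positive differences) after dropping zeros."""
    d = diff[diff != 0]
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p by DP over the null distribution of W+.

    Under the null each |difference| takes + or - with probability 1/2, so
    W+ is a sum over independent inclusion of each midrank.  Doubling the
    ranks makes them integers; the distribution is built by convolution.
    """
    r2 = np.rint(ranks * 2).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= 2.0 ** len(r2)
    w2 = int(round(w_plus * 2))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def global_shift_test(
    beta_treated: np.ndarray,
    beta_untreated: np.ndarray,
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Paired two-sample Wilcoxon signed-rank test on per-probe beta values.

    Zero differences are dropped; ties share midranks.  The p-value is exact
    (full enumeration of the null W+ distribution) for up to `exact_max_n`
    informative pairs and a normal approximation beyond.  All differences
    zero is degenerate: statistic 0, p = 1.
    """
    t = np.asarray(beta_treated, dtype=float)
    u = np.asarray(beta_untreated, dtype=float)
    if t.shape != u.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(t) & np.isfinite(u)
    diff = t[ok] - u[ok]
    d = diff[diff != 0]
    if len(d) == 0:
        return 0.0, 1.0
    w_plus, ranks = _signed_rank_statistic(diff)
    if len(d) <= exact_max_n:
        return w_plus, _exact_signed_rank_p(w_plus, ranks)
    res = stats.wilcoxon(d, alternative="two-sided", method="approx", correction=False)
    return w_plus, float(res.pvalue)


@dataclass
class DMResult:
    """Per-probe differential-methylation call."""

    probe_id: str
    beta_untreated: float
    beta_treated: float
    log2_fc: float
    dm_class: str  # hyper | hypo | unchanged


def classify_dm(
    beta_treated,
    beta_untreated,
    floor: float = 1e-6,
) -> pd.DataFrame:
    """Hyper/hypo classification by log2 fold change of beta, threshold |1|.

    log2_fc = log2(max(beta_treated, floor) / max(beta_untreated, floor));
    hyper iff log2_fc > 1 (more methylation after treatment), hypo iff
    log2_fc < -1, unchanged otherwise — the inequalities are strict, so a
    fold change of exactly 2 is unchanged.  Accepts scalars or aligned
    arrays/Series; returns a DataFrame (beta_untreated, beta_treated,
    log2_fc, dm_class).
    """
    t = np.atleast_1d(np.asarray(beta_treated, dtype=float))
    u = np.atleast_1d(np.asarray(beta_untreated, dtype=float))
    if ((t < 0) | (t > 1) | (u < 0) | (u > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    fc = np.log2(np.maximum(t, floor) / np.maximum(u, floor))
    cls = np.full(len(fc), "unchanged", dtype=object)
    cls[fc > 1] = "hyper"
    cls[fc < -1] = "hypo"
    index = beta_treated.index if isinstance(beta_treated, pd.Series) else None
    return pd.DataFrame(
        {"beta_untreated": u, "beta_treated": t, "log2_fc": fc, "dm_class": cls},
        index=index,
    )


def detect_cpg_islands(
    sequence: str,
    chrom: str = "chr1",
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
) -> IntervalSet:
    """CpG islands: merged min_len windows with GC > min_gc and obs/exp CpG > min_oe.

    Every min_len sliding window is tested for G+C fraction strictly above
    min_gc and observed/expected CpG ratio (N_CpG * L) / (N_C * N_G) strictly
    above min_oe (CpG dinucleotides counted fully inside the window);
    qualifying windows are unioned into maximal intervals.
    """
    L = len(sequence)
    if L < min_len:
        return IntervalSet()
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    cpg = (is_c[:-1] & is_g[1:]).astype(np.int64)
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cpg = np.concatenate([[0], np.cumsum(cpg)])
    starts = np.arange(0, L - min_len + 1)
    n_c = cum_c[starts + min_len] - cum_c[starts]
    n_g = cum_g[starts + min_len] - cum_g[starts]
    n_cpg = cum_cpg[starts + min_len - 1] - cum_cpg[starts]
    gc = (n_c + n_g) / min_len
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((n_c > 0) & (n_g > 0), n_cpg * min_len / (n_c * n_g), 0.0)
    good = (gc > min_gc) & (oe > min_oe)
    if not good.any():
        return IntervalSet()
    # union of qualifying [s, s + min_len) windows
    rows = []
    idx = np.flatnonzero(good)
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i <= prev + min_len:  # windows overlap or touch: same island
            prev = i
        else:
            rows.append((chrom, int(run_start), int(prev + min_len)))
            run_start = prev = i
    rows.append((chrom, int(run_start), int(prev + min_len)))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def annotate_island_context(
    pos: int | np.ndarray, islands: IntervalSet, chrom: str = "chr1"
) -> np.ndarray:
    """Island / shore / shelf / open sea label by distance to the nearest island.

    Inside an island -> "island"; within 2,000 bp of an edge (inclusive) ->
    "shore"; within 2,000-4,000 bp (inclusive) -> "shelf"; beyond -> "open
    sea".  With no islands everything is open sea.
    """
    pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
    sub = islands.for_chrom(chrom)
    out = np.full(len(pos), "open sea", dtype=object)
    if len(sub) == 0:
        return out
    starts = sub["start"].to_numpy(np.int64)
    ends = sub["end"].to_numpy(np.int64)
    d = np.full(len(pos), np.iinfo(np.int64).max)
    for s, e in zip(starts, ends):
        di = np.maximum(s - pos, 0) + np.maximum(pos - (e - 1), 0)
        d = np.minimum(d, di)
    out[d <= 4000] = "shelf"
    out[d <= 2000] = "shore"
    out[d == 0] = "island"
    return out


def annotate_functional_region(
    pos: int | np.ndarray,
    genes: pd.DataFrame,
    chrom: str | np.ndarray = "chr1",
) -> np.ndarray:
    """Functional label with precedence TSS200 > TSS1500 > 5'UTR > 1stExon > gene body > 3'UTR.

    `genes` carries one row per gene model: chrom, strand, tss, tx_start,
    tx_end and optional half-open feature intervals utr5_start/utr5_end,
    first_exon_start/first_exon_end, utr3_start/utr3_end.  TSS200/TSS1500 are
    the 200 bp / 1,500 bp windows immediately upstream of the TSS (strand
    aware, TSS excluded).  "Gene body" is the transcript interval minus the
    gene's own annotated 5'UTR/1stExon/3'UTR features (otherwise the lower
    precedence 3'UTR category could never be assigned).  Positions matching
    no gene category are "intergenic".
    """
    pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
    chroms = np.broadcast_to(np.asarray(chrom, dtype=object), pos.shape)
    out = np.full(len(pos), "intergenic", dtype=object)
    rank = {lab: i for i, lab in enumerate(FUNCTIONAL_PRECEDENCE)}
    best = np.full(len(pos), len(FUNCTIONAL_PRECEDENCE))

    def apply(mask: np.ndarray, label: str) -> None:
        upgrade = mask & (rank[label] < best)
        out[upgrade] = label
        best[upgrade] = rank[label]

    for g in genes.itertuples(index=False):
        on = chroms == g.chrom
        if not on.any():
            continue
        if g.strand == "+":
            tss200 = on & (pos >= g.tss - 200) & (pos < g.tss)
            tss1500 = on & (pos >= g.tss - 1500) & (pos < g.tss)
        else:
            tss200 = on & (pos > g.tss) & (pos <= g.tss + 200)
            tss1500 = on & (pos > g.tss) & (pos <= g.tss + 1500)
        apply(tss200, "TSS200")
        apply(tss1500, "TSS1500")
        in_feature = np.zeros(len(pos), dtype=bool)
        for field, label in (
            ("utr5", "5'UTR"),
            ("first_exon", "1stExon"),
            ("utr3", "3'UTR"),
        ):
            s = getattr(g, f"{field}_start", None)
            e = getattr(g, f"{field}_end", None)
            if s is not None and e is not None and not (pd.isna(s) or pd.isna(e)):
                mask = on & (pos >= int(s)) & (pos < int(e))
                apply(mask, label)
                in_feature |= mask
        apply(on & ~in_feature & (pos >= g.tx_start) & (pos < g.tx_end), "gene body")
    return out


def collapse_promoter(labels: np.ndarray) -> np.ndarray:
    """Merge TSS200/TSS1500 into a single 'promoter' category."""
    out = np.asarray(labels, dtype=object).copy()
    out[np.isin(out, list(PROMOTER_CATEGORIES))] = "promoter"
    return out


def _pct(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def summarize_dm(
    results: pd.DataFrame,
    annotations: pd.DataFrame,
    total: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Counts and two-decimal percentages of differential sites per category.

    `results` is a classify_dm output with a probe_id column; `annotations`
    maps probe_id to `functional` and `cpg_context` labels.  Percentages use
    denominator = total differential sites (hyper + hypo), round-half-up to
    two decimals.  Returns {"functional": ..., "cpg_context": ...} count
    tables plus a "total" entry.
    """
    diff = results[results["dm_class"].isin(["hyper", "hypo"])]
    merged = diff.merge(annotations, on="probe_id", how="left")
    if merged[["functional", "cpg_context"]].isna().any().any():
        raise ValueError("every differential probe must be annotated")
    n_total = total if total is not None else len(diff)
    out: dict[str, object] = {"total": n_total}
    for axis in ("functional", "cpg_context"):
        counts = merged[axis].value_counts()
        table = pd.DataFrame(
            {
                "count": counts,
                "percentage": [_pct(int(c), n_total) for c in counts],
            }
        )
        out[axis] = table
    return out


def hyper_hypo_gene_sets(
    results: pd.DataFrame,
    gene_map: pd.DataFrame,
) -> dict[str, object]:
    """Partition genes by their probes' differential classes.

    `gene_map` maps probe_id to gene (and optionally a `region` column for
    region-resolved reporting).  Returns hyper-only, hypo-only and "both"
    gene sets; for "both" genes, the (region, class) pairs their probes
    exhibit.
    """
    diff = results[results["dm_class"].isin(["hyper", "hypo"])]
    merged = diff.merge(gene_map, on="probe_id", how="left")
    if merged["gene"].isna().any():
        raise ValueError("gene_map must cover all differential probes")
    by_gene = merged.groupby("gene")["dm_class"].agg(set)
    hyper_only = {g for g, s in by_gene.items() if s == {"hyper"}}
    hypo_only = {g for g, s in by_gene.items() if s == {"hypo"}}
    both = {g for g, s in by_gene.items() if s == {"hyper", "hypo"}}
    region_pairs: dict[str, list[tuple[str, str]]] = {}
    if "region" in merged.columns:
        for g in sorted(both):
            sub = merged[merged["gene"] == g]
            region_pairs[g] = sorted(
                set(zip(sub["region"], sub["dm_class"]))
            )
    return {
        "hyper_only": hyper_only,
        "hypo_only": hypo_only,
        "both": both,
        "both_regions": region_pairs,
    }
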