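"""Site-anchored aggregation of nucleosome midpoints.

Metagene profiles around TSSs (strand-mirrored so downstream of the gene is
positive), promoter occupancy counts by expression class, enrichment ratios
over genome background around arbitrary site lists (DHS, CTCF, methylation
sites), and interval-overlap statistics for peak-set comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import MidpointTrack
from .intervals import IntervalSet, merge_intervals


@dataclass
class EnrichmentProfile:
    """Normalized midpoint density on an offset grid around anchored sites.

    `offsets` are window left edges relative to the anchor (strand-mirrored);
    `density` is the normalized value per window; `n_sites` the number of
    anchors aggregated; `normalization` a tag describing the scaling.
    """

    offsets: np.ndarray
    density: np.ndarray
    n_sites: int
    normalization: str = "per-million-midpoints"

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets)
        self.density = np.asarray(self.density, dtype=float)
        if len(self.offsets) != len(self.density):
            raise ValueError("offsets and density must align")
        if len(self.offsets) > 1 and not (np.diff(self.offsets) > 0).all():
            raise ValueError("offsets must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "density": self.density, "n_sites": self.n_sites}
        )


def expression_classes(expr: pd.DataFrame) -> pd.DataFrame:
    """Quartile (low/high) and decile labels for expressed genes.

    `expr` needs columns (gene_id, expression).  Genes with zero expression
    are excluded entirely.  Among the rest, ranks are assigned by a stable
    sort on (expression, gene_id): the bottom quarter is "low", the top
    quarter "high", and deciles run 1 (lowest) to 10 (highest).
    """
    if len(expr) == 0:
        raise ValueError("empty expression table")
    expressed = expr[expr["expression"] > 0].copy()
    if len(expressed) == 0:
        raise ValueError("no gene has positive expression")
    expressed = expressed.sort_values(
        ["expression", "gene_id"], kind="stable"
    ).reset_index(drop=True)
    n = len(expressed)
    rank = np.arange(n)
    quart = np.full(n, "mid", dtype=object)
    quart[rank < n // 4] = "low"
    quart[rank >= n - n // 4] = "high"
    decile = np.minimum(rank * 10 // n + 1, 10)
    expressed["quartile_class"] = quart
    expressed["decile"] = decile
    return expressed


def _anchored_offsets(
    midpoints: MidpointTrack,
    anchors: pd.DataFrame,
    flank_left: int,
    flank_right: int,
) -> np.ndarray:
    """Concatenated strand-mirrored midpoint offsets within [flank_left, flank_right).

    `anchors` needs columns (chrom, anchor, strand).  For '-' anchors the
    offset is anchor - midpoint so downstream of the feature is positive.
    """
    chunks = []
    for chrom in anchors["chrom"].unique():
        arr = midpoints.for_chrom(chrom)
        if len(arr) == 0:
            continue
        sub = anchors[anchors["chrom"] == chrom]
        for pos, strand in zip(sub["anchor"].to_numpy(np.int64), sub["strand"]):
            if strand == "-":
                # offset t = pos - m in [flank_left, flank_right)
                lo, hi = pos - flank_right + 1, pos - flank_left + 1
                m = arr[np.searchsorted(arr, lo) : np.searchsorted(arr, hi)]
                chunks.append(pos - m)
            else:
                lo, hi = pos + flank_left, pos + flank_right
                m = arr[np.searchsorted(arr, lo) : np.searchsorted(arr, hi)]
                chunks.append(m - pos)
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(chunks)


def _anchor_frame(sites: IntervalSet, require_strand: bool, force_plus: bool) -> pd.DataFrame:
    df = sites.df
    if require_strand and not force_plus and (df["strand"] == ".").any():
        raise ValueError(
            "anchors must be stranded (pass force_plus=True to treat '.' as '+')"
        )
    anchors = df[["chrom", "strand"]].copy()
    anchors.loc[anchors["strand"] == ".", "strand"] = "+"
    anchors["anchor"] = sites.anchors()
    return anchors


def tss_profile(
    midpoints: MidpointTrack,
    tss: IntervalSet,
    flank: int = 1000,
    step: int = 5,
    force_plus: bool = False,
    per_site_mean: bool = False,
) -> EnrichmentProfile:
    """Metagene midpoint profile around TSSs in step-sized windows.

    Counts midpoints in windows of `step` bp covering [-flank, +flank) around
    each TSS, mirrored so transcription runs left-to-right.  Default
    normalization pools counts over sites and scales to midpoints-per-million
    (total track midpoints); per_site_mean=True instead divides by the number
    of sites.
    """
    anchors = _anchor_frame(tss, require_strand=True, force_plus=force_plus)
    offs = _anchored_offsets(midpoints, anchors, -flank, flank)
    edges = np.arange(-flank, flank + step, step)
    counts, _ = np.histogram(offs, bins=edges)
    if per_site_mean:
        density = counts / max(len(tss), 1)
        tag = "per-site-mean"
    else:
        total = midpoints.total_midpoints
        density = counts * (1e6 / total) if total else counts.astype(float)
        tag = "per-million-midpoints"
    return EnrichmentProfile(edges[:-1], density, n_sites=len(tss), normalization=tag)


def promoter_occupancy(
    midpoints: MidpointTrack,
    tss: IntervalSet,
    region: tuple[int, int] = (-500, 250),
) -> pd.Series:
    """Midpoint count per gene in the strand-aware window [region) around its TSS.

    The default window spans 500 bp upstream to 250 bp downstream of the TSS,
    half-open on the downstream edge.  Index of the returned Series is the
    interval `name` column (gene ids).
    """
    anchors = _anchor_frame(tss, require_strand=True, force_plus=False)
    lo, hi = region
    counts = np.zeros(len(anchors), dtype=np.int64)
    pos = anchors["anchor"].to_numpy(np.int64)
    strands = anchors["strand"].to_numpy()
    chrom_arr = anchors["chrom"].to_numpy()
    for chrom in anchors["chrom"].unique():
        arr = midpoints.for_chrom(chrom)
        idx = np.flatnonzero(chrom_arr == chrom)
        for i in idx:
            if strands[i] == "-":
                a, b = pos[i] - hi + 1, pos[i] - lo + 1
            else:
                a, b = pos[i] + lo, pos[i] + hi
            counts[i] = np.searchsorted(arr, b) - np.searchsorted(arr, a)
    return pd.Series(counts, index=tss.df["name"].to_numpy(), name="occupancy")


def site_enrichment_ratio(
    midpoints: MidpointTrack,
    sites: IntervalSet,
    genome_length: int,
    width: int = 2000,
    step: int = 50,
    force_plus: bool = True,
) -> EnrichmentProfile:
    """Midpoint density around sites as a ratio over the genome-wide mean.

    Counts midpoints in `step`-bp windows across a `width`-bp region centered
    on each site, then divides each window's count by the genome-average
    expectation for an equal-width slice pooled over the same number of
    sites: ratio 1 means background level.
    """
    if len(sites) == 0:
        raise ValueError("empty site list")
    total = midpoints.total_midpoints
    if total == 0 or genome_length <= 0:
        raise ValueError("zero genome-wide midpoint density")
    flank = width // 2
    anchors = _anchor_frame(sites, require_strand=False, force_plus=force_plus)
    offs = _anchored_offsets(midpoints, anchors, -flank, flank)
    edges = np.arange(-flank, flank + step, step)
    counts, _ = np.histogram(offs, bins=edges)
    expected_per_window = total / genome_length * step * len(sites)
    return EnrichmentProfile(
        edges[:-1],
        counts / expected_per_window,
        n_sites=len(sites),
        normalization="ratio-over-genome-mean",
    )


def _shared_bases(starts, ends, ref_merged) -> np.ndarray:
    """Bases each [start, end) interval shares with a merged reference set."""
    if len(ref_merged) == 0:
        return np.zeros(len(starts), dtype=np.int64)
    rs, re = ref_merged[:, 0], ref_merged[:, 1]
    # cumulative reference coverage up to each merged-interval end
    cum = np.concatenate([[0], np.cumsum(re - rs)])

    def cov_upto(x: np.ndarray) -> np.ndarray:
        i = np.searchsorted(rs, x, side="right")
        inside = np.clip(x - rs[np.maximum(i - 1, 0)], 0, (re - rs)[np.maximum(i - 1, 0)])
        inside[i == 0] = 0
        return cum[np.maximum(i - 1, 0)] + inside

    return cov_upto(np.asarray(ends)) - cov_upto(np.asarray(starts))


def peak_overlap(
    query: IntervalSet,
    reference: IntervalSet,
    min_frac: float = 0.10,
    reciprocal: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Flag query peaks sharing >= min_frac of their length with reference peaks.

    The denominator is the query peak length; reciprocal=True additionally
    requires the shared bases to reach min_frac of the best-matching merged
    reference interval.  Returns (per-peak table, overall overlapping
    fraction).
    """
    rows = []
    for chrom in query.chroms:
        q = query.for_chrom(chrom)
        r = reference.for_chrom(chrom)
        merged = merge_intervals(r["start"].to_numpy(), r["end"].to_numpy())
        shared = _shared_bases(q["start"].to_numpy(), q["end"].to_numpy(), merged)
        qlen = (q["end"] - q["start"]).to_numpy()
        ok = shared >= min_frac * qlen
        if reciprocal and len(merged):
            # require the same fraction of some overlapping reference interval
            for j, (s, e) in enumerate(zip(q["start"], q["end"])):
                if not ok[j]:
                    continue
                hit = merged[(merged[:, 0] < e) & (merged[:, 1] > s)]
                if len(hit) == 0:
                    ok[j] = False
                    continue
                frac = max(
                    (min(e, he) - max(s, hs)) / (he - hs) for hs, he in hit
                )
                ok[j] = frac >= min_frac
        for (idx, row), sh, o in zip(q.iterrows(), shared, ok):
            rows.append((row["chrom"], row["start"], row["end"], row["name"], int(sh), bool(o)))
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "shared_bases", "overlaps"]
    )
    fraction = float(table["overlaps"].mean()) if len(table) else 0.0
    return table, fraction


def replicate_reproducibility(
    peaksets: list[IntervalSet], min_frac: float = 0.10
) -> pd.DataFrame:
    """Pairwise overlapping fractions among replicate peak sets.

    Entry (i, j) is the fraction of set i's peaks overlapping set j by at
    least min_frac of their length; the diagonal is 1.
    """
    if len(peaksets) < 2:
        raise ValueError("need at least two peak sets")
    k = len(peaksets)
    mat = np.ones((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            _, frac = peak_overlap(peaksets[i], peaksets[j], min_frac=min_frac)
            mat[i, j] = frac
    return pd.DataFrame(mat, index=range(k), columns=range(k))


def peaks_near_tss(
    peaks: IntervalSet, tss: IntervalSet, max_dist: int = 1000
) -> set[str]:
    """Gene ids whose TSS lies within max_dist bp of a peak edge (inclusive).

    A peak containing the TSS is distance 0.  TSS records are anchored
    strand-aware (minus-strand TSS at end - 1); gene ids come from the `name`
    column.
    """
    hits: set[str] = set()
    anchors = tss.anchors()
    tss_df = tss.df
    for chrom in tss.chroms:
        p = peaks.for_chrom(chrom)
        if len(p) == 0:
            continue
        starts = p["start"].to_numpy(np.int64)
        ends = p["end"].to_numpy(np.int64)
        mask = (tss_df["chrom"] == chrom).to_numpy()
        for pos, name in zip(anchors[mask], tss_df["name"].to_numpy()[mask]):
            # distance from point to each interval: 0 if inside
            d = np.maximum(starts - pos, 0) + np.maximum(pos - (ends - 1), 0)
            if (d <= max_dist).any():
                hits.add(name)
    return hits
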