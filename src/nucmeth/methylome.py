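"""Strand-resolved methylation-site classification and enrichment by class.

Pairs plus/minus strand cytosine calls into CpG and CWG sites, classifies
each site as homo- or hemimethylated and as highly (>10 methylated reads) or
moderately methylated, and profiles nucleosome-midpoint enrichment around
each of the eight resulting classes, ranked by their central enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import MidpointTrack
from .intervals import IntervalSet
from .profiles import EnrichmentProfile, site_enrichment_ratio
from .synth import GenomeModel

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "coverage", "pct_meth"]


def methylated_read_mass(calls: pd.DataFrame, wins: IntervalSet) -> np.ndarray:
    """Total methylated reads per window: sum of coverage * pct_meth / 100.

    Each call contributes its methylated-read mass to the single window
    containing its position.
    """
    mass = calls["coverage"].to_numpy(float) * calls["pct_meth"].to_numpy(float) / 100.0
    out = np.zeros(len(wins), dtype=float)
    df = wins.df
    for chrom in wins.chroms:
        cmask = (calls["chrom"] == chrom).to_numpy()
        if not cmask.any():
            continue
        pos = calls["pos"].to_numpy(np.int64)[cmask]
        m = mass[cmask]
        wmask = (df["chrom"] == chrom).to_numpy()
        starts = df["start"].to_numpy(np.int64)[wmask]
        ends = df["end"].to_numpy(np.int64)[wmask]
        # windows are non-overlapping and sorted: locate by start
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
        win_rows = np.flatnonzero(wmask)
        np.add.at(out, win_rows[idx[ok]], m[ok])
    return out


def pair_strands(
    calls: pd.DataFrame, genome: GenomeModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join plus/minus strand calls into per-site records.

    A plus-strand CpG cytosine at p pairs with the minus-strand cytosine at
    p + 1; a plus-strand CWG cytosine at p pairs with the minus-strand
    cytosine at p + 2.  Calls whose declared context disagrees with the
    genome sequence are dropped (logged); calls with no partner are returned
    in the unpaired table.

    Returns (paired, unpaired).  `paired` has one row per site with columns
    (chrom, pos, context, cov_plus, pct_plus, cov_minus, pct_minus).
    """
    if genome.sequence is None:
        raise ValueError("genome sequence required to verify contexts")

    def context_ok(chrom: str, pos: int, strand: str, ctx: str) -> bool:
        seq = genome.sequence[chrom]
        try:
            if ctx == "CpG":
                if strand == "+":
                    return seq[pos : pos + 2] == "CG"
                return seq[pos - 1 : pos + 1] == "CG"
            if ctx == "CWG":
                if strand == "+":
                    return seq[pos] == "C" and seq[pos + 1] in "AT" and seq[pos + 2] == "G"
                return seq[pos - 2] == "C" and seq[pos - 1] in "AT" and seq[pos] == "G"
        except IndexError:
            return False
        return False

    valid = np.fromiter(
        (
            context_ok(c, p, s, x)
            for c, p, s, x in zip(
                calls["chrom"], calls["pos"], calls["strand"], calls["context"]
            )
        ),
        dtype=bool,
        count=len(calls),
    )
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("pair_strands: dropped %d context-mismatched calls", n_bad)
    calls = calls[valid]

    plus = calls[calls["strand"] == "+"]
    minus = calls[calls["strand"] == "-"]
    dup = minus.duplicated(subset=["chrom", "pos", "context"], keep="first")
    if dup.any():
        logger.info("pair_strands: %d duplicate minus-strand calls ignored", int(dup.sum()))
        minus = minus[~dup]
    offset = plus["context"].map({"CpG": 1, "CWG": 2})
    plus_k = plus.assign(site_pos=plus["pos"], partner=plus["pos"] + offset)
    minus_k = minus.set_index(["chrom", "pos", "context"])
    rows, unpaired_idx = [], []
    matched_minus: set[tuple] = set()
    for row in plus_k.itertuples():
        key = (row.chrom, row.partner, row.context)
        if key in minus_k.index:
            m = minus_k.loc[key]
            rows.append(
                (row.chrom, row.site_pos, row.context,
                 row.coverage, row.pct_meth, int(m["coverage"]), float(m["pct_meth"]))
            )
            matched_minus.add(key)
        else:
            unpaired_idx.append(row.Index)
    unpaired_minus = [
        i for i, (c, p, x) in zip(
            minus.index, zip(minus["chrom"], minus["pos"], minus["context"])
        )
        if (c, p, x) not in matched_minus
    ]
    paired = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "context", "cov_plus", "pct_plus", "cov_minus", "pct_minus"],
    )
    unpaired = calls.loc[sorted(unpaired_idx + unpaired_minus)]
    return paired, unpaired


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def classify_sites(
    paired: pd.DataFrame,
    meth_threshold: float = 50.0,
    high_reads: int = 10,
) -> pd.DataFrame:
    """Classify paired sites by symmetry and methylated-read level.

    A strand is methylated iff its pct_meth >= meth_threshold.  Sites with
    both strands methylated are "homo", exactly one "hemi"; sites with
    neither are excluded.  The methylated-read count is
    round-half-up(sum over strands of coverage * pct/100); level is "high"
    iff that count is strictly greater than `high_reads`, else "moderate"
    (exactly 10 reads is moderate).  Class labels follow the
    hemi/homo-CpG/CWG-1/10 convention (1 = moderate, 10 = high).
    """
    meth_p = paired["pct_plus"] >= meth_threshold
    meth_m = paired["pct_minus"] >= meth_threshold
    keep = meth_p | meth_m
    sub = paired[keep].copy()
    meth_p, meth_m = meth_p[keep], meth_m[keep]
    sub["symmetry"] = np.where(meth_p & meth_m, "homo", "hemi")
    mass = (
        sub["cov_plus"] * sub["pct_plus"] / 100.0
        + sub["cov_minus"] * sub["pct_minus"] / 100.0
    )
    sub["methylated_reads"] = [ _round_half_up(v) for v in mass ]
    sub["level"] = np.where(sub["methylated_reads"] > high_reads, "high", "moderate")
    level_tag = np.where(sub["level"] == "high", "10", "1")
    sub["class"] = sub["symmetry"] + "-" + sub["context"].map(
        {"CpG": "CpG", "CWG": "CWG"}
    ) + level_tag
    return sub.reset_index(drop=True)


@dataclass
class ClassEnrichment:
    """Per-class enrichment profiles with a binding-strength ordering."""

    profiles: dict[str, EnrichmentProfile]
    central_ratio: dict[str, float]
    ordering: list[str]
    distinct: bool


def enrichment_by_class(
    midpoints: MidpointTrack,
    classes: pd.DataFrame,
    genome_length: int,
    width: int = 2000,
    step: int = 50,
    central_halfwidth: int = 250,
    indistinct_tol: float = 0.1,
) -> ClassEnrichment:
    """Enrichment-over-background profile per methylation class, ranked.

    Classes are ranked by the mean ratio over the central
    +/- central_halfwidth bp of their profile, descending.  If the spread of
    central ratios is below `indistinct_tol` the ordering is flagged as not
    distinct (e.g. uniform background).  Empty classes are skipped with a
    warning.
    """
    profiles: dict[str, EnrichmentProfile] = {}
    central: dict[str, float] = {}
    for label, sub in classes.groupby("class", sort=False):
        if len(sub) == 0:
            continue
        sites = IntervalSet(
            pd.DataFrame(
                {
                    "chrom": sub["chrom"],
                    "start": sub["pos"],
                    "end": sub["pos"] + 1,
                }
            )
        )
        prof = site_enrichment_ratio(
            midpoints, sites, genome_length, width=width, step=step
        )
        profiles[label] = prof
        mask = (prof.offsets >= -central_halfwidth) & (
            prof.offsets + step <= central_halfwidth
        )
        central[label] = float(prof.density[mask].mean())
    if not profiles:
        logger.warning("enrichment_by_class: no non-empty classes")
        return ClassEnrichment({}, {}, [], False)
    ordering = sorted(central, key=lambda k: (-central[k], k))
    spread = max(central.values()) - min(central.values())
    return ClassEnrichment(profiles, central, ordering, distinct=spread > indistinct_tol)
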