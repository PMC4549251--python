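"""Genome tiling and windowed signal correlation.

Tiles the genome into fixed-width windows (2 kb by default), summarizes
coverage tracks and midpoint counts per window, forms the log-normalized
PARP1 density (midpoints over total-nucleosome background), and reports
Pearson correlations between window-level signals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import CoverageTrack, MidpointTrack
from .intervals import IntervalSet
from .synth import GenomeModel


def tile_genome(genome: GenomeModel, width: int = 2000) -> IntervalSet:
    """Consecutive [k*width, (k+1)*width) tiles per chromosome.

    The final partial tile (if any) is kept; its name carries a ':partial'
    suffix.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    rows = []
    for chrom in genome.chrom_names:
        length = genome.chrom_lengths[chrom]
        starts = np.arange(0, length, width)
        for k, s in enumerate(starts):
            e = min(s + width, length)
            tag = f"{chrom}:w{k}" + (":partial" if e - s < width else "")
            rows.append((chrom, int(s), int(e), ".", 0.0, tag))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "score", "name"]))


def window_mean_signal(track: CoverageTrack, wins: IntervalSet) -> np.ndarray:
    """Arithmetic mean of per-base track values within each window."""
    out = np.empty(len(wins), dtype=float)
    df = wins.df
    for chrom in wins.chroms:
        vals = track.for_chrom(chrom)
        cum = np.concatenate([[0.0], np.cumsum(vals)])
        mask = (df["chrom"] == chrom).to_numpy()
        s = df["start"].to_numpy(np.int64)[mask]
        e = df["end"].to_numpy(np.int64)[mask]
        out[mask] = (cum[e] - cum[s]) / (e - s)
    return out


def window_counts(track: MidpointTrack, wins: IntervalSet) -> np.ndarray:
    """Midpoint count per window (a midpoint belongs to exactly one tile)."""
    out = np.zeros(len(wins), dtype=np.int64)
    df = wins.df
    for chrom in wins.chroms:
        arr = track.for_chrom(chrom)
        mask = (df["chrom"] == chrom).to_numpy()
        s = df["start"].to_numpy(np.int64)[mask]
        e = df["end"].to_numpy(np.int64)[mask]
        out[mask] = np.searchsorted(arr, e) - np.searchsorted(arr, s)
    return out


def normalized_density(
    parp: MidpointTrack,
    background: MidpointTrack,
    wins: IntervalSet,
    pseudocount: int = 1,
    drop_empty: bool = True,
) -> pd.DataFrame:
    """log2((parp + pc) / (background + pc)) per window.

    Windows where both counts are zero are excluded by default (the ratio is
    undefined as a signal there); pass drop_empty=False to keep them at
    log2(1) = 0.
    """
    if background.total_midpoints == 0:
        raise ValueError("background track has no midpoints")
    p = window_counts(parp, wins)
    b = window_counts(background, wins)
    value = np.log2((p + pseudocount) / (b + pseudocount))
    df = wins.df[["chrom", "start", "end"]].copy()
    df["parp_count"] = p
    df["background_count"] = b
    df["log2_density"] = value
    if drop_empty:
        df = df[(p > 0) | (b > 0)].reset_index(drop=True)
    return df


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t transform.

    Pairs with a missing value in either vector are dropped; constant input
    raises ValueError (the coefficient is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_matrix(signals: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r over all numeric signal columns of a window table."""
    cols = signals.columns
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r, _ = pearson_corr(signals[a].to_numpy(), signals[b].to_numpy())
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat
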