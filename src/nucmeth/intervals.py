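"""Stranded genomic interval sets.

A thin, deterministic container for site lists (TSSs, peaks, DHS/CTCF sites,
CpG islands, genome tiles).  Records are kept in a pandas DataFrame with
0-based half-open coordinates, sorted by (chrom, start, end); all overlap and
proximity queries elsewhere in the package run on per-chromosome sorted numpy
arrays pulled from here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

COLUMNS = ["chrom", "start", "end", "strand", "score", "name"]

VALID_STRANDS = frozenset({"+", "-", "."})


@dataclass
class IntervalSet:
    """Sorted set of stranded genomic intervals (0-based, half-open)."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COLUMNS))

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in COLUMNS:
            if col not in df.columns:
                if col == "strand":
                    df[col] = "."
                elif col == "score":
                    df[col] = 0.0
                elif col == "name":
                    df[col] = ""
                else:
                    raise ValueError(f"IntervalSet requires a '{col}' column")
        df = df[COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"interval start >= end at record {bad}")
        if len(df) and not df["strand"].isin(VALID_STRANDS).all():
            raise ValueError("strand must be one of '+', '-', '.'")
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        self.df = df

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], columns: list[str] | None = None
    ) -> "IntervalSet":
        cols = columns or ["chrom", "start", "end", "strand", "score", "name"]
        return cls(pd.DataFrame.from_records(list(records), columns=cols))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[pd.Series]:
        return (row for _, row in self.df.iterrows())

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def total_bases(self) -> int:
        """Sum of interval lengths after merging overlaps (union size)."""
        total = 0
        for chrom in self.chroms:
            sub = self.for_chrom(chrom)
            merged = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
            total += int((merged[:, 1] - merged[:, 0]).sum())
        return total

    def anchors(self) -> np.ndarray:
        """Strand-aware anchor position per record.

        '+' and '.' records anchor at `start`; '-' records anchor at `end - 1`
        (the biological start of a minus-strand feature).
        """
        minus = (self.df["strand"] == "-").to_numpy()
        pos = self.df["start"].to_numpy().copy()
        pos[minus] = self.df["end"].to_numpy()[minus] - 1
        return pos


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent sorted-by-start intervals; returns (n, 2) array."""
    if len(starts) == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    starts = np.asarray(starts)[order]
    ends = np.asarray(ends)[order]
    out: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], int(e))
        else:
            out.append([int(s), int(e)])
    return np.asarray(out, dtype=np.int64)
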