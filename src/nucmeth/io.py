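"""Readers and writers for the package's tabular formats.

BED and TSV interval lists, bedGraph coverage, fixed-step wiggle,
NGSmethDB-style methylation-call tables, probe tables, and truth tables.
Internal coordinates are uniformly 0-based half-open; 1-based conversion
happens only at these boundaries, behind explicit flags.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import CoverageTrack, MidpointTrack
from .intervals import COLUMNS, IntervalSet


class FormatError(ValueError):
    pass


def read_intervals(
    path: str | Path, fmt: str = "BED", one_based: bool = False
) -> IntervalSet:
    """Read an interval list from BED (or headered TSV) into an IntervalSet.

    BED columns beyond (chrom, start, end) are optional: name, score, strand.
    With one_based=True, starts are shifted by -1 on read (closed 1-based
    input).  Malformed lines raise FormatError with the line number.
    """
    path = Path(path)
    if fmt not in {"BED", "TSV"}:
        raise FormatError(f"unknown format {fmt!r}")
    rows = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    start_line = 0
    header: list[str] | None = None
    if fmt == "TSV":
        header = lines[0].split("\t")
        start_line = 1
    for lineno, line in enumerate(lines[start_line:], start=start_line + 1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if fmt == "TSV":
            rec = dict(zip(header, parts))
            chrom, s, e = rec["chrom"], rec["start"], rec["end"]
            name = rec.get("name", "")
            score = rec.get("score", 0)
            strand = rec.get("strand", ".")
        else:
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, s, e = parts[:3]
            name = parts[3] if len(parts) > 3 else ""
            score = parts[4] if len(parts) > 4 else 0
            strand = parts[5] if len(parts) > 5 else "."
        try:
            start, end = int(s), int(e)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        if one_based:
            start -= 1
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        try:
            score = float(score)
        except ValueError:
            score = 0.0
        rows.append((chrom, start, end, strand, score, name))
    return IntervalSet(pd.DataFrame(rows, columns=COLUMNS))


def write_intervals(
    sites: IntervalSet, path: str | Path, fmt: str = "BED", one_based: bool = False
) -> None:
    df = sites.df.copy()
    if one_based:
        df["start"] = df["start"] + 1
    if fmt == "BED":
        bed = df[["chrom", "start", "end", "name", "score", "strand"]]
        bed.to_csv(path, sep="\t", header=False, index=False)
    elif fmt == "TSV":
        df.to_csv(path, sep="\t", index=False)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def write_midpoints_bed(track: MidpointTrack, path: str | Path) -> None:
    """Midpoints as 1 bp BED intervals."""
    with open(path, "w") as fh:
        for chrom in sorted(track.midpoints):
            for m in track.midpoints[chrom]:
                fh.write(f"{chrom}\t{m}\t{m + 1}\n")


def read_midpoints_bed(path: str | Path, source_label: str = "") -> MidpointTrack:
    sites = read_intervals(path, fmt="BED")
    out = {
        chrom: sites.for_chrom(chrom)["start"].to_numpy(np.int64)
        for chrom in sites.chroms
    }
    return MidpointTrack(out, source_label=source_label or str(path))


def write_bedgraph(track: CoverageTrack, path: str | Path, precision: int = 6) -> None:
    """Run-length-merged bedGraph; zero-valued runs are written too, so the
    file round-trips the full track."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = np.round(track.values[chrom], precision)
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals) != 0)
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [len(vals)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{vals[s]:.{precision}f}\n")


def read_bedgraph(path: str | Path, chrom_lengths: dict[str, int]) -> CoverageTrack:
    values = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split("\t")
            values[chrom][int(s) : int(e)] = float(v)
    return CoverageTrack(values)


def write_wiggle(track: CoverageTrack, path: str | Path, step: int = 1) -> None:
    """Fixed-step wiggle (UCSC browser parity)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            fh.write(f"fixedStep chrom={chrom} start=1 step={step} span={step}\n")
            vals = track.values[chrom]
            for i in range(0, len(vals), step):
                fh.write(f"{vals[i:i + step].mean():.6f}\n")


def write_pairs_bed(pairs: pd.DataFrame, path: str | Path) -> None:
    """6-column BED-like pair table (chrom, start, end, name, length, strand)."""
    pairs[["chrom", "start", "end", "name", "length", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_pairs_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "length", "strand"],
    )
    return df


def write_methylation_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_methylation_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_genomestudio_export(path: str | Path) -> pd.DataFrame:
    """Reader for GenomeStudio-style probe export columns.

    Expects TargetID, CHR, MAPINFO and per-sample `<sample>.AVG_Beta` /
    `<sample>.Detection Pval` columns; returns the package's long-form probe
    table (probe_id, chrom, pos, sample, beta, detection_p).
    """
    wide = pd.read_csv(path, sep="\t")
    betas = [c for c in wide.columns if c.endswith(".AVG_Beta")]
    rows = []
    for bcol in betas:
        sample = bcol[: -len(".AVG_Beta")]
        pcol = f"{sample}.Detection Pval"
        sub = pd.DataFrame(
            {
                "probe_id": wide["TargetID"],
                "chrom": wide["CHR"].astype(str),
                "pos": wide["MAPINFO"].astype(np.int64),
                "sample": sample,
                "beta": wide[bcol].astype(float),
                "detection_p": wide[pcol].astype(float) if pcol in wide else 0.0,
            }
        )
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)
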