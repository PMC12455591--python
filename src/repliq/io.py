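"""Readers and writers for BED, bedGraph, chrom.sizes, FASTA and count tables.

All writers emit tab-separated, newline-terminated records. bedGraph stands in
for bigWig throughout: a :class:`~repliq.genomic.CoverageTrack` serializes as
run-length-merged bedGraph records on its bin grid and reads back exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genomic import CoverageTrack, GenomeLayout, GenomicInterval, IntervalSet

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
]


class BedParseError(ValueError):
    pass


def read_chrom_sizes(path) -> GenomeLayout:
    sizes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            sizes.append((parts[0], int(parts[1])))
    return GenomeLayout(sizes)


def write_chrom_sizes(layout: GenomeLayout, path) -> Path:
    with open(path, "w") as fh:
        for chrom in layout:
            fh.write(f"{chrom}\t{layout[chrom]}\n")
    return Path(path)


def read_bed(path, layout: Optional[GenomeLayout] = None) -> IntervalSet:
    """Read a 3-6 column BED file (0-based half-open; strand optional)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return IntervalSet(intervals, layout=layout)


def _fmt_score(x: float) -> str:
    return format(x, ".10g")


def write_bed(intervals: IntervalSet, path, columns: int = 6) -> Path:
    """Write BED3 or BED6 (``columns`` 3 or 6)."""
    with open(path, "w") as fh:
        for iv in intervals:
            if columns <= 3:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}"
                    f"\t{_fmt_score(iv.score)}\t{iv.strand}\n"
                )
    return Path(path)


def read_bedgraph(
    path,
    bin_size: int,
    layout: GenomeLayout,
    units: str = "raw",
    rebin: bool = False,
) -> CoverageTrack:
    """Read bedGraph into a :class:`CoverageTrack` on a ``bin_size`` grid.

    Records must be non-overlapping. Records aligned to the grid are assigned
    directly; off-grid records require ``rebin=True`` and contribute by
    length-weighted mean to every bin they touch. Unspecified positions are 0.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        comment="#",
    )
    acc = {c: np.zeros(layout.n_bins(c, bin_size)) for c in layout}
    cov = {c: np.zeros(layout.n_bins(c, bin_size)) for c in layout}
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in layout:
            raise BedParseError(f"{path}: unknown chromosome {chrom!r}")
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        vals = sub["value"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise BedParseError(f"{path}: overlapping records on {chrom}")
        if ends[-1] > layout[chrom]:
            raise BedParseError(f"{path}: record beyond end of {chrom}")
        chrom_len = layout[chrom]
        on_grid = (starts % bin_size == 0) & (
            (ends % bin_size == 0) | (ends == chrom_len)
        )
        if not rebin and not on_grid.all():
            raise BedParseError(
                f"{path}: off-grid record on {chrom} (bin_size={bin_size}); "
                "pass rebin=True to re-bin by length-weighted mean"
            )
        a, c = acc[chrom], cov[chrom]
        for s, e, v in zip(starts, ends, vals):
            b0, b1 = s // bin_size, -(-e // bin_size)
            for b in range(b0, b1):
                lo = max(s, b * bin_size)
                hi = min(e, (b + 1) * bin_size)
                a[b] += v * (hi - lo)
                c[b] += hi - lo
    data = {}
    for chrom in layout:
        with np.errstate(invalid="ignore"):
            vals = np.where(cov[chrom] > 0, acc[chrom] / np.maximum(cov[chrom], 1), 0.0)
        data[chrom] = vals
    return CoverageTrack(layout, bin_size, data, units=units)


def write_bedgraph(track: CoverageTrack, path, merge_equal: bool = True) -> Path:
    """Write a track as bedGraph; consecutive equal-valued bins are merged
    into one record (``merge_equal=False`` writes one record per bin).
    NaN bins are omitted."""
    with open(path, "w") as fh:
        bs = track.bin_size
        for chrom in track.layout:
            arr = track.data[chrom]
            chrom_len = track.layout[chrom]
            n = arr.size
            if merge_equal:
                # run boundaries where the value changes (NaN-safe)
                same = (arr[1:] == arr[:-1]) | (np.isnan(arr[1:]) & np.isnan(arr[:-1]))
                breaks = np.flatnonzero(~same) + 1
                run_starts = np.concatenate([[0], breaks])
                run_ends = np.concatenate([breaks, [n]])
            else:
                run_starts = np.arange(n)
                run_ends = run_starts + 1
            for b0, b1 in zip(run_starts, run_ends):
                v = arr[b0]
                if np.isnan(v):
                    continue
                s = int(b0) * bs
                e = min(int(b1) * bs, chrom_len)
                fh.write(f"{chrom}\t{s}\t{e}\t{format(v, '.12g')}\n")
    return Path(path)


def read_fasta(path) -> dict[str, str]:
    """Read a (small) FASTA into name -> sequence. For random access on large
    genomes use :mod:`pyfaidx` directly."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> Path:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return Path(path)


def read_counts(path) -> pd.DataFrame:
    """Read a TSV count table (first columns chrom/start/end or a region id)."""
    return pd.read_csv(path, sep="\t")


def write_counts(df: pd.DataFrame, path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
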