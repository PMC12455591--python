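"""Core genomic containers and interval arithmetic.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Binned signal lives in :class:`CoverageTrack`, which carries bedGraph semantics
(one value per fixed-size bin, last bin truncated at the chromosome end).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "IntervalSet",
    "CoverageTrack",
    "bin_genome",
    "merge_within",
    "filter_min_length",
    "central_window",
    "count_overlaps",
    "metaprofile",
]

#: units tags under which negative track values are legal
SIGNED_UNITS = frozenset({"log-ratio", "difference", "rti"})


class GenomeLayout(Mapping[str, int]):
    """Chromosome name -> length (bp). Names unique, lengths positive."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        names = [c for c, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for chrom, length in items:
            if int(length) <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        self._sizes: Dict[str, int] = {c: int(n) for c, n in items}

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:
        return f"GenomeLayout({self._sizes!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self._sizes == other._sizes

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self._sizes[chrom] // bin_size)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = field(default=".", compare=False)
    score: float = field(default=0.0, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`, sorted by (chrom, start).

    Construction sorts; validation against a :class:`GenomeLayout` is optional
    and checks that every interval lies inside its chromosome.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        layout: Optional[GenomeLayout] = None,
    ):
        self.intervals: List[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        if layout is not None:
            self.validate(layout)

    def validate(self, layout: GenomeLayout) -> None:
        for iv in self.intervals:
            if iv.chrom not in layout:
                raise ValueError(f"interval chromosome {iv.chrom!r} not in layout")
            if iv.end > layout[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {layout[iv.chrom]}"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    @property
    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def total_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def by_chrom(self) -> Dict[str, List[GenomicInterval]]:
        out: Dict[str, List[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def subset(self, mask: Sequence[bool]) -> "IntervalSet":
        return IntervalSet(iv for iv, keep in zip(self.intervals, mask) if keep)

    def union(self, *others: "IntervalSet") -> "IntervalSet":
        ivs = list(self.intervals)
        for o in others:
            ivs.extend(o.intervals)
        return IntervalSet(ivs)


class CoverageTrack:
    """Per-chromosome binned signal with fixed bin size (bedGraph semantics).

    ``data[chrom][i]`` is the value over ``[i*bin_size, min((i+1)*bin_size, L))``.
    The ``units`` tag records normalization state; values must be non-negative
    unless the tag is one of ``log-ratio``, ``difference`` or ``rti``.
    """

    def __init__(
        self,
        layout: GenomeLayout,
        bin_size: int,
        data: Optional[Mapping[str, np.ndarray]] = None,
        units: str = "raw",
        allow_nan: bool = True,
    ):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.layout = layout
        self.bin_size = int(bin_size)
        self.units = units
        if data is None:
            self.data = {
                c: np.zeros(layout.n_bins(c, bin_size)) for c in layout
            }
        else:
            self.data = {}
            for chrom in layout:
                if chrom not in data:
                    raise ValueError(f"missing data for chromosome {chrom!r}")
                arr = np.asarray(data[chrom], dtype=float)
                want = layout.n_bins(chrom, bin_size)
                if arr.shape != (want,):
                    raise ValueError(
                        f"{chrom}: expected {want} bins, got {arr.shape}"
                    )
                self.data[chrom] = arr
        self._check_values(allow_nan=allow_nan)

    def _check_values(self, allow_nan: bool = True) -> None:
        signed = self.units in SIGNED_UNITS
        for chrom, arr in self.data.items():
            finite = np.isfinite(arr)
            if not allow_nan and not finite.all():
                raise ValueError(f"{chrom}: non-finite values in track")
            if np.isinf(arr).any():
                raise ValueError(f"{chrom}: infinite values in track")
            if not signed and np.nanmin(arr, initial=0.0) < 0:
                raise ValueError(
                    f"{chrom}: negative values not allowed with units {self.units!r}"
                )

    def copy(self, units: Optional[str] = None) -> "CoverageTrack":
        return CoverageTrack(
            self.layout,
            self.bin_size,
            {c: v.copy() for c, v in self.data.items()},
            units=units or self.units,
        )

    def values(self) -> np.ndarray:
        """All bin values concatenated in layout order."""
        return np.concatenate([self.data[c] for c in self.layout])

    def same_grid(self, other: "CoverageTrack") -> bool:
        return self.bin_size == other.bin_size and self.layout == other.layout

    def rebin(self, new_bin_size: int, reducer: str = "mean") -> "CoverageTrack":
        """Re-bin to a coarser grid; ``new_bin_size`` must be a multiple."""
        if new_bin_size % self.bin_size != 0:
            raise ValueError("new bin size must be a multiple of the current one")
        k = new_bin_size // self.bin_size
        out = {}
        for chrom in self.layout:
            arr = self.data[chrom]
            n_out = self.layout.n_bins(chrom, new_bin_size)
            pad = n_out * k - arr.size
            padded = np.concatenate([arr, np.full(pad, np.nan)]) if pad else arr
            mat = padded.reshape(n_out, k)
            if reducer == "mean":
                out[chrom] = np.nanmean(mat, axis=1)
            elif reducer == "sum":
                out[chrom] = np.nansum(mat, axis=1)
            elif reducer == "max":
                out[chrom] = np.nanmax(mat, axis=1)
            else:
                raise ValueError(f"unknown reducer {reducer!r}")
        return CoverageTrack(self.layout, new_bin_size, out, units=self.units)

    def scale(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            self.layout,
            self.bin_size,
            {c: v * factor for c, v in self.data.items()},
            units=self.units,
        )

    def interval_sum(self, iv: GenomicInterval) -> float:
        """Length-weighted sum of signal over an interval (bin values are
        treated as densities per bin; partial bins contribute fractionally)."""
        arr = self.data[iv.chrom]
        b0 = iv.start // self.bin_size
        b1 = -(-iv.end // self.bin_size)
        total = 0.0
        for b in range(b0, b1):
            lo = max(iv.start, b * self.bin_size)
            hi = min(iv.end, (b + 1) * self.bin_size)
            total += arr[b] * (hi - lo) / self.bin_size
        return float(total)

    def interval_mean(self, iv: GenomicInterval) -> float:
        arr = self.data[iv.chrom]
        b0 = iv.start // self.bin_size
        b1 = -(-iv.end // self.bin_size)
        return float(np.nanmean(arr[b0:b1]))


# ---------------------------------------------------------------------------
# interval operations


def bin_genome(layout: GenomeLayout, bin_size: int) -> IntervalSet:
    """Tile every chromosome with ``bin_size`` bins (last bin truncated)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    out = []
    for chrom in layout:
        length = layout[chrom]
        for start in range(0, length, bin_size):
            out.append(GenomicInterval(chrom, start, min(start + bin_size, length)))
    return IntervalSet(out)


def merge_within(intervals: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge intervals on the same chromosome separated by ``<= max_gap`` bp.

    Touching or overlapping intervals (gap <= 0) are always merged. Idempotent.
    """
    merged: List[GenomicInterval] = []
    for chrom, ivs in intervals.by_chrom().items():
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(merged)


def filter_min_length(intervals: IntervalSet, min_len: int) -> IntervalSet:
    """Keep intervals of length >= ``min_len`` (boundary inclusive)."""
    return IntervalSet(iv for iv in intervals if len(iv) >= min_len)


def central_window(
    iv: GenomicInterval, width: int, layout: Optional[GenomeLayout] = None
) -> GenomicInterval:
    """The ``width`` bp window centered on the interval midpoint.

    Intervals shorter than ``width`` are returned unchanged; the window is
    clipped to chromosome bounds when a layout is given.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if len(iv) <= width:
        return iv
    mid = iv.midpoint
    start = mid - width // 2
    end = start + width
    if start < 0:
        start, end = 0, width
    if layout is not None:
        chrom_len = layout[iv.chrom]
        if end > chrom_len:
            end = chrom_len
            start = max(0, end - width)
    return GenomicInterval(iv.chrom, start, end, iv.name, iv.score, iv.strand)


def count_overlaps(query: IntervalSet, features: IntervalSet) -> np.ndarray:
    """Number of features overlapping (>= 1 bp) each query interval.

    Half-open semantics: abutting intervals do not overlap.
    """
    feat = features.by_chrom()
    starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in feat.items()}
    ends = {c: np.sort([iv.end for iv in ivs]) for c, ivs in feat.items()}
    counts = np.zeros(len(query), dtype=int)
    for i, q in enumerate(query):
        if q.chrom not in starts:
            continue
        n_start_before_qend = np.searchsorted(starts[q.chrom], q.end, side="left")
        n_end_before_qstart = np.searchsorted(ends[q.chrom], q.start, side="right")
        counts[i] = n_start_before_qend - n_end_before_qstart
    return counts


def overlap_fraction(query: IntervalSet, features: IntervalSet) -> np.ndarray:
    """Fraction of each query interval covered by the union of features."""
    merged = merge_within(features, 0).by_chrom() if len(features) else {}
    out = np.zeros(len(query))
    for i, q in enumerate(query):
        covered = 0
        for f in merged.get(q.chrom, []):
            covered += max(0, min(q.end, f.end) - max(q.start, f.start))
        out[i] = covered / len(q)
    return out


def _point_rows(
    track: CoverageTrack,
    centers: List[tuple[str, int]],
    upstream: int,
    downstream: int,
) -> np.ndarray:
    bs = track.bin_size
    n_cols = (upstream + downstream) // bs
    offsets = -upstream + (np.arange(n_cols) * bs) + bs // 2
    rows = np.full((len(centers), n_cols), np.nan)
    for i, (chrom, center) in enumerate(centers):
        arr = track.data[chrom]
        pos = center + offsets
        idx = pos // bs
        ok = (pos >= 0) & (pos < track.layout[chrom])
        rows[i, ok] = arr[idx[ok]]
    return rows


def _scaled_body_rows(
    track: CoverageTrack,
    anchors: IntervalSet,
    upstream: int,
    downstream: int,
    body_cols: int,
) -> np.ndarray:
    bs = track.bin_size
    up_cols = upstream // bs
    down_cols = downstream // bs
    rows = np.full((len(anchors), up_cols + body_cols + down_cols), np.nan)
    for i, iv in enumerate(anchors):
        arr = track.data[iv.chrom]
        chrom_len = track.layout[iv.chrom]
        # flank columns sample the track on its own grid
        up_pos = iv.start - upstream + np.arange(up_cols) * bs + bs // 2
        down_pos = iv.end + np.arange(down_cols) * bs + bs // 2
        for j, pos in enumerate(up_pos):
            if 0 <= pos < chrom_len:
                rows[i, j] = arr[pos // bs]
        # body rescaled to body_cols by sampling body_cols evenly spaced points
        body_pos = iv.start + (np.arange(body_cols) + 0.5) / body_cols * len(iv)
        body_idx = np.minimum(body_pos.astype(int) // bs, arr.size - 1)
        rows[i, up_cols : up_cols + body_cols] = arr[body_idx]
        for j, pos in enumerate(down_pos):
            if 0 <= pos < chrom_len:
                rows[i, up_cols + body_cols + j] = arr[pos // bs]
    return rows


def metaprofile(
    track: CoverageTrack,
    anchors: IntervalSet,
    upstream: int,
    downstream: int,
    mode: str = "point-centered",
    body_cols: int = 50,
):
    """Signal matrix around anchors plus mean and standard-error vectors.

    ``point-centered`` rows cover ``[midpoint - upstream, midpoint + downstream)``
    on the track's bin grid; ``scaled-body`` rescales each anchor body to
    ``body_cols`` columns with flank columns on the native grid. Positions off
    the chromosome are NaN and excluded from the column means.

    Returns ``(matrix, mean, stderr)``.
    """
    if mode == "point-centered":
        centers = [(iv.chrom, iv.midpoint) for iv in anchors]
        rows = _point_rows(track, centers, upstream, downstream)
    elif mode == "scaled-body":
        rows = _scaled_body_rows(track, anchors, upstream, downstream, body_cols)
    else:
        raise ValueError(f"unknown metaprofile mode {mode!r}")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(rows, axis=0)
        n = np.sum(~np.isnan(rows), axis=0)
        sd = np.nanstd(rows, axis=0, ddof=1)
    stderr = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return rows, mean, stderr
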