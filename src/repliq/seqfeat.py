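"""Sequence-derived tracks: nucleotide content and poly(dA)/poly(dT) tracts.

Replication origins tend to be flanked by antiparallel dA/dT tracts that
destabilize nucleosomes; LTR bodies are AT-depleted with AT-rich flanks.
This module turns raw sequence into per-bin nucleotide-content tracks (5 bp
bins, percent scale) and 0/100 tract masks (runs of >= 20 bp at >= 75% of one
nucleotide), plus strand-aware profiles at annotated elements.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .genomic import CoverageTrack, GenomeLayout, IntervalSet, metaprofile

__all__ = [
    "nucleotide_content",
    "poly_tract_mask",
    "combined_tract_mask",
    "stranded_profile",
]

_CODE = np.full(256, 4, dtype=np.uint8)    # 4 = ambiguous
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i                      # lower case


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def nucleotide_content(
    sequences: Mapping[str, str], bin_size: int = 5
) -> Dict[str, CoverageTrack]:
    """Percent content of each nucleotide per ``bin_size`` bp bin.

    Returns tracks keyed "A", "C", "G", "T" and "AT" (= A% + T%).
    Ambiguous bases (N) are excluded from the denominator; fully ambiguous
    bins are NaN. Percentages over unambiguous sequence sum to 100 per bin.
    """
    if not sequences or any(len(s) == 0 for s in sequences.values()):
        raise ValueError("empty sequence")
    layout = GenomeLayout({c: len(s) for c, s in sequences.items()})
    per_base: Dict[str, Dict[str, np.ndarray]] = {b: {} for b in "ACGT"}
    for chrom, seq in sequences.items():
        codes = _encode(seq)
        n_bins = layout.n_bins(chrom, bin_size)
        pad = n_bins * bin_size - codes.size
        if pad:
            codes = np.concatenate([codes, np.full(pad, 4, dtype=np.uint8)])
        mat = codes.reshape(n_bins, bin_size)
        counts = np.stack([(mat == i).sum(axis=1) for i in range(4)])
        denom = counts.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(denom > 0, 100.0 * counts / np.maximum(denom, 1), np.nan)
        for i, b in enumerate("ACGT"):
            per_base[b][chrom] = pct[i]
    tracks = {
        b: CoverageTrack(layout, bin_size, per_base[b], units="percent")
        for b in "ACGT"
    }
    at = {
        c: per_base["A"][c] + per_base["T"][c] for c in layout
    }
    tracks["AT"] = CoverageTrack(layout, bin_size, at, units="percent")
    return tracks


def poly_tract_mask(
    sequences: Mapping[str, str],
    nucleotide: str,
    min_len: int = 20,
    min_frac: float = 0.75,
) -> CoverageTrack:
    """Per-base 0/100 mask of poly-nucleotide tracts.

    A position scores 100 iff it carries the target ``nucleotide`` and lies
    inside some window of length ``min_len`` whose composition of that
    nucleotide is >= ``min_frac`` (fixed-length windows suffice: any longer
    qualifying tract contains qualifying ``min_len``-mers). Marking only the
    tract-composing nucleotide keeps a pure minimal tract scored exactly
    over its own extent. Ambiguous bases count toward window length but
    never toward the target.
    """
    if nucleotide not in "ACGT":
        raise ValueError("nucleotide must be one of A, C, G, T")
    if min_len < 1 or not (0 < min_frac <= 1):
        raise ValueError("min_len >= 1 and 0 < min_frac <= 1 required")
    target = "ACGT".index(nucleotide)
    layout = GenomeLayout({c: len(s) for c, s in sequences.items()})
    need = min_frac * min_len
    data = {}
    for chrom, seq in sequences.items():
        codes = _encode(seq)
        n = codes.size
        mask = np.zeros(n, dtype=np.uint8)
        if n >= min_len:
            is_t = (codes == target).astype(np.int32)
            csum = np.concatenate([[0], np.cumsum(is_t)])
            win = csum[min_len:] - csum[:-min_len]       # count per start
            hits = np.flatnonzero(win >= need)
            if hits.size:
                # mark [s, s + min_len) for each qualifying start via diff trick
                delta = np.zeros(n + 1, dtype=np.int32)
                np.add.at(delta, hits, 1)
                np.add.at(delta, hits + min_len, -1)
                covered = np.cumsum(delta[:-1]) > 0
                mask = (covered & (codes == target)).astype(np.uint8)
        data[chrom] = mask * 100.0
    return CoverageTrack(layout, 1, data, units="percent")


def combined_tract_mask(
    sequences: Mapping[str, str], min_len: int = 20, min_frac: float = 0.75
) -> CoverageTrack:
    """Union of the poly(dA) and poly(dT) masks."""
    a = poly_tract_mask(sequences, "A", min_len, min_frac)
    t = poly_tract_mask(sequences, "T", min_len, min_frac)
    data = {c: np.maximum(a.data[c], t.data[c]) for c in a.layout}
    return CoverageTrack(a.layout, 1, data, units="percent")


def stranded_profile(
    track: CoverageTrack,
    elements: IntervalSet,
    upstream: int,
    downstream: int,
    body_cols: int = 50,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled-body metaprofile oriented by element strand.

    Rows of minus-strand elements are reversed before averaging so that
    "upstream" is always 5' of the element. Elements without orientation
    ('.') are an error. Returns ``(matrix, mean, stderr)``.
    """
    for iv in elements:
        if iv.strand not in ("+", "-"):
            raise ValueError(
                f"element {iv.chrom}:{iv.start}-{iv.end} has no strand; "
                "orientation is required for stranded profiles"
            )
    # swap flank widths for minus-strand rows so reversal restores them
    plus = IntervalSet(iv for iv in elements if iv.strand == "+")
    minus = IntervalSet(iv for iv in elements if iv.strand == "-")
    pieces = []
    if len(plus):
        rows, _, _ = metaprofile(
            track, plus, upstream, downstream, "scaled-body", body_cols
        )
        pieces.append(rows)
    if len(minus):
        rows, _, _ = metaprofile(
            track, minus, downstream, upstream, "scaled-body", body_cols
        )
        pieces.append(rows[:, ::-1])
    if not pieces:
        raise ValueError("no elements to profile")
    if upstream != downstream and len(pieces) == 2:
        # asymmetric flanks cannot be pooled across strands column-by-column
        raise ValueError("stranded profiles require upstream == downstream")
    mat = np.vstack(pieces)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
        n = np.sum(~np.isnan(mat), axis=0)
    stderr = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return mat, mean, stderr
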