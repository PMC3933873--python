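"""Exhaustive ungapped overlap search between the mates of a read pair.

Every relative placement of the reverse-complemented reverse read
against the forward read is scored; no seed heuristics and no gaps.
A placement is described by the offset d of the first base of the
reverse-complemented reverse read relative to the first base of the
forward read:

* d >= 0 — the usual geometry: the fragment is at least as long as the
  reverse read, the overlap is a suffix of the forward read against a
  prefix of the reverse-complemented reverse read, and the implied
  fragment length is d + L2.
* d < 0 — the fragment is shorter than a read, both reads run past its
  ends, the overlap IS the fragment and the implied fragment length is
  the overlap length.

The placement with maximal assembly score wins; ties prefer the longer
overlap, then the longer implied fragment, then the larger offset, which
makes the search fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import Read, ReadPair
from .scoring import (
    BaseFrequencies,
    ScoringParams,
    ScoringTables,
    encode_bases,
    per_base_score,
    quality_to_error_prob,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(read: Read) -> Read:
    """Reverse-complement the bases (N stays N) and reverse the qualities."""
    return Read(
        id=read.id,
        bases=read.bases.translate(_COMPLEMENT)[::-1],
        quals=read.quals[::-1].copy(),
    )


@dataclass(frozen=True)
class OverlapPlacement:
    """One ungapped relative placement; see the module docstring for d."""

    offset: int
    overlap_len: int
    implied_fragment_len: int

    @classmethod
    def from_offset(cls, d: int, len1: int, len2: int) -> "OverlapPlacement":
        if d >= 0:
            n = min(len1 - d, len2)
            frag = d + len2
        else:
            n = min(len1, len2 + d)
            frag = n
        if n < 1:
            raise ValueError(f"offset {d} gives no overlap for lengths {len1}, {len2}")
        return cls(offset=d, overlap_len=n, implied_fragment_len=frag)

    def columns(self, len1: int, len2: int) -> tuple[slice, slice]:
        """Index ranges of the overlap columns in the forward read and in the
        reverse-complemented reverse read."""
        i0 = max(0, self.offset)
        return slice(i0, i0 + self.overlap_len), slice(i0 - self.offset, i0 - self.offset + self.overlap_len)


@dataclass(frozen=True)
class ScoredOverlap:
    placement: OverlapPlacement
    assembly_score: float


def enumerate_placements(len1: int, len2: int, min_overlap: int = 1) -> list[OverlapPlacement]:
    """All placements with overlap length >= min_overlap, in offset order."""
    if len1 < 1 or len2 < 1:
        raise ValueError("read lengths must be >= 1")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    out = []
    for d in range(-(len2 - 1), len1):
        n = min(len1 - d, len2) if d >= 0 else min(len1, len2 + d)
        if n >= min_overlap:
            out.append(OverlapPlacement.from_offset(d, len1, len2))
    return out


def placement_overlap_lengths(len1: int, len2: int, min_overlap: int = 1) -> np.ndarray:
    """Overlap lengths of all admissible placements (with multiplicity)."""
    d = np.arange(-(len2 - 1), len1)
    n = np.where(d >= 0, np.minimum(len1 - d, len2), np.minimum(len1, len2 + d))
    return n[n >= min_overlap]


def assembly_score(
    forward: Read,
    reverse_rc: Read,
    placement: OverlapPlacement,
    params: ScoringParams,
    freqs: BaseFrequencies,
) -> float:
    """Sum of per-column scores over the overlap of one placement."""
    len1, len2 = len(forward), len(reverse_rc)
    expect = OverlapPlacement.from_offset(placement.offset, len1, len2)
    if expect != placement:
        raise ValueError(f"placement {placement} inconsistent with lengths {len1}, {len2}")
    sl1, sl2 = placement.columns(len1, len2)
    total = 0.0
    for x, y, qx, qy in zip(
        forward.bases[sl1], reverse_rc.bases[sl2], forward.quals[sl1], reverse_rc.quals[sl2]
    ):
        total += per_base_score(
            x, y, quality_to_error_prob(int(qx)), quality_to_error_prob(int(qy)), params, freqs
        )
    return total


def oes_score(
    forward: Read, reverse_rc: Read, placement: OverlapPlacement, tables: ScoringTables
) -> float:
    """Observed expected alignment score of one placement via table lookups.

    Always posterior-weighted (uses the ``oes_*`` tables), independent of
    the search mode; equals the scalar column loop up to float summation
    order.
    """
    sl1, sl2 = placement.columns(len(forward), len(reverse_rc))
    f_code = encode_bases(forward.bases[sl1])
    r_code = encode_bases(reverse_rc.bases[sl2])
    fq = np.minimum(forward.quals[sl1], tables.max_quality).astype(np.intp)
    rq = np.minimum(reverse_rc.quals[sl2], tables.max_quality).astype(np.intp)
    col = np.where(
        f_code == r_code,
        tables.oes_match[fq, rq],
        tables.oes_mismatch[fq, rq],
    )
    f_n = f_code == 4
    r_n = r_code == 4
    if f_n.any() or r_n.any():
        col = np.where(f_n & ~r_n, tables.oes_n_called[np.minimum(r_code, 3), rq], col)
        col = np.where(~f_n & r_n, tables.oes_n_called[np.minimum(f_code, 3), fq], col)
        col = np.where(f_n & r_n, tables.oes_n_both, col)
    return float(col.sum())


def _score_matrix(forward: Read, reverse_rc: Read, tables: ScoringTables) -> np.ndarray:
    """Per-cell score of forward base i against reverse-complement base j."""
    f_code = encode_bases(forward.bases)
    r_code = encode_bases(reverse_rc.bases)
    fq = np.minimum(forward.quals, tables.max_quality).astype(np.intp)
    rq = np.minimum(reverse_rc.quals, tables.max_quality).astype(np.intp)

    cell = np.where(
        f_code[:, None] == r_code[None, :],
        tables.match[fq[:, None], rq[None, :]],
        tables.mismatch[fq[:, None], rq[None, :]],
    )
    f_n = f_code == 4
    r_n = r_code == 4
    if f_n.any() or r_n.any():
        # one uncalled: score depends on the called base and its quality
        n_vs_r = tables.n_called[np.minimum(r_code, 3), rq]  # forward is N
        f_vs_n = tables.n_called[np.minimum(f_code, 3), fq]  # reverse is N
        cell = np.where(f_n[:, None] & ~r_n[None, :], n_vs_r[None, :], cell)
        cell = np.where(~f_n[:, None] & r_n[None, :], f_vs_n[:, None], cell)
        cell = np.where(f_n[:, None] & r_n[None, :], tables.n_both, cell)
    return cell


def _diagonal_sums(cell: np.ndarray) -> np.ndarray:
    """Sum of each diagonal d = i - j, returned for d = -(L2-1) .. L1-1.

    Accumulation happens in ravel order, i.e. in increasing i within a
    diagonal — the same order as a per-column loop over the overlap.
    """
    len1, len2 = cell.shape
    i = np.arange(len1)[:, None]
    j = np.arange(len2)[None, :]
    diag = (i - j + len2 - 1).ravel()
    return np.bincount(diag, weights=cell.ravel(), minlength=len1 + len2 - 1)


def find_best_overlap(
    pair: ReadPair,
    params: ScoringParams,
    freqs: BaseFrequencies,
    min_overlap: int = 1,
    tables: Optional[ScoringTables] = None,
    reverse_rc: Optional[Read] = None,
) -> Optional[ScoredOverlap]:
    """Score every placement and return the maximizer of the assembly score.

    Returns ``None`` when no placement reaches ``min_overlap`` bases.
    Ties on the score prefer the larger overlap, then the larger implied
    fragment length, then the larger offset.
    """
    len1, len2 = len(pair.forward), len(pair.reverse)
    if len1 < 1 or len2 < 1:
        raise ValueError("both reads must be non-empty")
    if min_overlap > min(len1, len2):
        return None
    if tables is None:
        tables = ScoringTables(params, freqs, max_quality=int(
            max(93, pair.forward.quals.max(initial=0), pair.reverse.quals.max(initial=0))
        ))
    if reverse_rc is None:
        reverse_rc = reverse_complement(pair.reverse)

    scores = _diagonal_sums(_score_matrix(pair.forward, reverse_rc, tables))
    d = np.arange(-(len2 - 1), len1)
    n = np.where(d >= 0, np.minimum(len1 - d, len2), np.minimum(len1, len2 + d))
    frag = np.where(d >= 0, d + len2, n)
    ok = n >= min_overlap
    d, n, frag, scores = d[ok], n[ok], frag[ok], scores[ok]
    # lexsort: primary key last -> max score, ties to larger n, then larger
    # implied fragment, then larger offset (fully deterministic)
    best = np.lexsort((d, frag, n, scores))[-1]
    placement = OverlapPlacement(int(d[best]), int(n[best]), int(frag[best]))
    return ScoredOverlap(placement=placement, assembly_score=float(scores[best]))
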