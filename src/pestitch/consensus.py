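"""Consensus construction for an accepted overlap placement.

Within the overlap, each column is collapsed by four rules: identical
called bases keep the base with the product of the two error
probabilities (errors are independent); different called bases keep the
base with the smaller error probability (ties keep the forward base);
one uncalled base defers to the called one; two uncalled bases stay N
with the larger error probability.  Outside the overlap the flanks are
copied unchanged for standard geometry (offset d >= 0); for d < 0 the
bases beyond the implied fragment are read-through (adapter/noise) and
are discarded, so the merged read is the consensus alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import QualityEncoding, Read, ReadPair
from .overlap import (
    OverlapPlacement,
    ScoredOverlap,
    find_best_overlap,
    oes_score,
    reverse_complement,
)
from .scoring import (
    BaseFrequencies,
    ScoringParams,
    ScoringTables,
    error_prob_to_quality,
    quality_to_error_prob,
    random_match_prob,
)
from .significance import TestConfig, TestOutcome, decide, observed_expected_score


@dataclass
class MergeResult:
    """Outcome of merging one read pair.

    ``status`` is ``merged``, ``unmerged`` (no admissible overlap, or the
    significance test rejected) or ``discarded`` (set later by the
    post-merge filters).  Score fields are NaN when no placement was
    admissible; ``p`` is the 1.0 sentinel when the test is disabled.
    """

    status: str
    merged: Optional[Read] = None
    placement: Optional[OverlapPlacement] = None
    assembly_score: float = float("nan")
    oes: float = float("nan")
    p: float = 1.0


def merge_base(x: str, y: str, e_x: float, e_y: float) -> tuple[str, float]:
    """Collapse one overlap column to (base, combined error probability)."""
    x_n, y_n = x == "N", y == "N"
    if x_n and y_n:
        return "N", max(e_x, e_y)
    if x_n:
        return y, e_y
    if y_n:
        return x, e_x
    if x == y:
        return x, e_x * e_y
    return (x, e_x) if e_x <= e_y else (y, e_y)


def build_merged_read(
    pair: ReadPair,
    placement: OverlapPlacement,
    encoding: QualityEncoding = QualityEncoding(),
    quality_cap: Optional[int] = None,
    reverse_rc: Optional[Read] = None,
) -> Read:
    """Assemble the merged read for an accepted placement.

    The merged length always equals the implied fragment length, and
    every combined quality is capped at ``quality_cap`` (default: the
    encoding's maximum).
    """
    if reverse_rc is None:
        reverse_rc = reverse_complement(pair.reverse)
    len1, len2 = len(pair.forward), len(reverse_rc)
    if OverlapPlacement.from_offset(placement.offset, len1, len2) != placement:
        raise ValueError(f"placement {placement} inconsistent with lengths {len1}, {len2}")
    cap = encoding.max_quality if quality_cap is None else min(quality_cap, encoding.max_quality)

    sl1, sl2 = placement.columns(len1, len2)
    bases = []
    errs = np.empty(placement.overlap_len)
    e1 = quality_to_error_prob(pair.forward.quals[sl1])
    e2 = quality_to_error_prob(reverse_rc.quals[sl2])
    for i, (x, y) in enumerate(zip(pair.forward.bases[sl1], reverse_rc.bases[sl2])):
        b, e = merge_base(x, y, float(e1[i]), float(e2[i]))
        bases.append(b)
        errs[i] = e
    cons_quals = error_prob_to_quality(errs, max_quality=cap)

    if placement.offset >= 0:
        d = placement.offset
        n = placement.overlap_len
        merged_bases = pair.forward.bases[:d] + "".join(bases) + reverse_rc.bases[n:]
        merged_quals = np.concatenate(
            [pair.forward.quals[:d], cons_quals, reverse_rc.quals[n:]]
        )
        # forward read-through past a short fragment (d + len2 < len1) is
        # implicitly dropped because the overlap covers the whole tail
        merged_bases = merged_bases[: placement.implied_fragment_len]
        merged_quals = merged_quals[: placement.implied_fragment_len]
    else:
        merged_bases = "".join(bases)
        merged_quals = cons_quals
    return Read(id=pair.forward.id, bases=merged_bases, quals=merged_quals)


def merge_pair(
    pair: ReadPair,
    params: ScoringParams = ScoringParams(),
    freqs: Optional[BaseFrequencies] = None,
    test: TestConfig = TestConfig(),
    encoding: QualityEncoding = QualityEncoding(),
    min_overlap: int = 1,
    tables: Optional[ScoringTables] = None,
    quality_cap: Optional[int] = None,
) -> MergeResult:
    """Full per-pair workflow: search every placement, test, build consensus.

    All failure modes (no admissible placement, non-significant overlap)
    yield an ``unmerged`` result; the outcome is deterministic for fixed
    inputs and configuration.
    """
    if freqs is None:
        freqs = BaseFrequencies.uniform()
    reverse_rc = reverse_complement(pair.reverse)
    best = find_best_overlap(
        pair, params, freqs, min_overlap=min_overlap, tables=tables, reverse_rc=reverse_rc
    )
    if best is None:
        return MergeResult(status="unmerged")
    if tables is not None:
        oes = oes_score(pair.forward, reverse_rc, best.placement, tables)
    else:
        oes = observed_expected_score(pair, best.placement, freqs, params, reverse_rc=reverse_rc)
    outcome = decide(
        oes,
        best.placement,
        (len(pair.forward), len(pair.reverse)),
        random_match_prob(freqs),
        test,
        params,
    )
    if not outcome.significant:
        return MergeResult(
            status="unmerged",
            placement=best.placement,
            assembly_score=best.assembly_score,
            oes=oes,
            p=outcome.p,
        )
    merged = build_merged_read(
        pair, best.placement, encoding=encoding, quality_cap=quality_cap, reverse_rc=reverse_rc
    )
    return MergeResult(
        status="merged",
        merged=merged,
        placement=best.placement,
        assembly_score=best.assembly_score,
        oes=oes,
        p=outcome.p,
    )
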