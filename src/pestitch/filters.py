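"""Post-merge quality filters and four-way output classification.

Filters run after merging.  Merged reads are checked against the
length bounds and the uncalled-base proportion; unmerged reads are
first trimmed at the first run of two consecutive low-quality bases,
then checked against the same bounds.  Each mate of an unmerged pair
is filtered independently: one mate can be discarded while its partner
survives.  Reverse mates are written in their as-sequenced orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consensus import MergeResult
from .io import Read, ReadPair


@dataclass(frozen=True)
class FilterConfig:
    """Trimming threshold and output-length/uncalled-base bounds.

    ``trim_min_quality`` 0 disables trimming; ``max_length`` 0 disables
    the upper length bound; ``max_uncalled_fraction`` 1.0 admits any
    proportion of N.
    """

    trim_min_quality: int = 0
    min_length: int = 50
    max_length: int = 0
    max_uncalled_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")
        if self.max_length != 0 and self.max_length < self.min_length:
            raise ValueError("max_length must be 0 (off) or >= min_length")
        if not 0.0 <= self.max_uncalled_fraction <= 1.0:
            raise ValueError("max_uncalled_fraction must be in [0, 1]")


def trim_low_quality(read: Read, trim_min_quality: int) -> Read:
    """Truncate before the first two consecutive bases below the threshold.

    Idempotent; a read with no such doublet is returned unchanged.
    """
    if trim_min_quality <= 0 or len(read) < 2:
        return read
    low = read.quals < trim_min_quality
    doublet = low[:-1] & low[1:]
    if not doublet.any():
        return read
    cut = int(np.argmax(doublet))
    return Read(id=read.id, bases=read.bases[:cut], quals=read.quals[:cut].copy())


def uncalled_fraction(read: Read) -> float:
    """Proportion of uncalled (N) bases; undefined for an empty read."""
    if len(read) == 0:
        raise ValueError("uncalled fraction of an empty read is undefined")
    return read.bases.count("N") / len(read)


def _passes(read: Read, config: FilterConfig) -> bool:
    if len(read) < max(config.min_length, 1):
        # zero-length reads are never emitted to the unassembled/assembled files
        return False
    if config.max_length and len(read) > config.max_length:
        return False
    return uncalled_fraction(read) <= config.max_uncalled_fraction


def classify(
    result: MergeResult, pair: ReadPair, config: FilterConfig
) -> list[tuple[str, Read]]:
    """Route one pair's outcome to the four output categories.

    Returns (category, record) tuples with category one of
    ``assembled`` / ``forward`` / ``reverse`` / ``discarded``.  Every
    input pair contributes either its merged product once or both mates
    once each, so reads are conserved across the four files.
    """
    if result.status == "merged":
        assert result.merged is not None
        category = "assembled" if _passes(result.merged, config) else "discarded"
        return [(category, result.merged)]
    out = []
    for category, mate in (("forward", pair.forward), ("reverse", pair.reverse)):
        trimmed = trim_low_quality(mate, config.trim_min_quality)
        out.append((category if _passes(trimmed, config) else "discarded", trimmed))
    return out
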