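"""Synthetic paired-end read simulator and evaluation metrics.

The simulator emulates the standard read-simulation protocol for
benchmarking mergers: fragments are sampled from reference sequences
with normally distributed lengths, fixed-length reads are taken from
both fragment ends, per-position quality profiles drive
quality-dependent substitution errors, and — when a fragment is shorter
than a read — the reads run past the fragment end and are padded with
uniform random bases at the lowest quality (the "read-through" case).

References are uniform-random synthetic sequences: overlap merging is
content-agnostic, and random references keep spurious overlaps rare so
that correctness and false-positive rates measure the algorithm rather
than reference paralogy.  The true fragment behind every pair is
retained as ground truth for the evaluation metrics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .consensus import MergeResult
from .io import QualityEncoding, Read, ReadPair, write_fastq

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults follow the benchmark protocol this package is tested
    against: 100-bp reads, fragment-length standard deviation 10 bp, two
    linearly decaying quality profiles (forward 38→20, reverse 36→18)
    standing in for the empirical rise of Illumina error rates along the
    read, and quality-0 uniform-random padding when a fragment is
    shorter than a read.
    """

    n_pairs: int = 1000
    read_length: int = 100
    fragment_mean: float = 180.0
    fragment_sd: float = 10.0
    n_refs: int = 20
    ref_length: int = 800
    quality_start: tuple[int, int] = (38, 36)
    quality_end: tuple[int, int] = (20, 18)
    padding_quality: int = 0
    error_free: bool = False
    errors_only_in_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1 or self.fragment_mean < 1:
            raise ValueError("read_length and fragment_mean must be >= 1")
        if self.read_length > self.ref_length:
            raise ValueError(
                f"read_length {self.read_length} exceeds ref_length {self.ref_length}"
            )
        if self.n_pairs < 0 or self.n_refs < 1:
            raise ValueError("n_pairs must be >= 0 and n_refs >= 1")

    def quality_profile(self, mate: int) -> np.ndarray:
        """Integer quality per read position for mate 0 (forward) or 1 (reverse)."""
        return np.rint(
            np.linspace(self.quality_start[mate], self.quality_end[mate], self.read_length)
        ).astype(np.int16)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated pair."""

    pair_id: int
    ref_id: str
    fragment_start: int
    fragment_length: int
    mergeable: bool
    fragment: str  # true fragment sequence


def _overlap_window(frag_len: int, read_len: int) -> tuple[int, int]:
    """Read positions covered by both mates (same window in either mate's
    own coordinates); empty when the fragment is at least twice the read."""
    lo = max(0, frag_len - read_len)
    hi = min(read_len, frag_len)
    return lo, max(lo, hi)


def _simulate(
    config: SimConfig, force_no_overlap: bool
) -> tuple[list[ReadPair], list[SimTruth]]:
    rng = np.random.default_rng(config.seed)
    L = config.read_length
    if force_no_overlap and config.ref_length < 2 * L:
        raise ValueError("no-overlap simulation needs ref_length >= 2 * read_length")
    refs = [rng.integers(0, 4, size=config.ref_length, dtype=np.int8) for _ in range(config.n_refs)]
    profiles = (config.quality_profile(0), config.quality_profile(1))

    pairs: list[ReadPair] = []
    truths: list[SimTruth] = []
    for pid in range(config.n_pairs):
        ref_idx = int(rng.integers(config.n_refs))
        frag_len = int(np.clip(round(rng.normal(config.fragment_mean, config.fragment_sd)),
                               1, config.ref_length))
        if force_no_overlap:
            frag_len = max(frag_len, 2 * L)
        start = int(rng.integers(0, config.ref_length - frag_len + 1))
        frag = refs[ref_idx][start : start + frag_len]

        mates = []
        for mate in range(2):
            core = frag[:L] if mate == 0 else (3 - frag[max(0, frag_len - L):])[::-1]
            n_pad = L - len(core)
            pad = rng.integers(0, 4, size=n_pad, dtype=np.int8)
            codes = np.concatenate([core, pad]).astype(np.int8)
            quals = profiles[mate].copy()
            quals[len(core):] = config.padding_quality

            err_mask = np.zeros(L, dtype=bool)
            err_mask[: len(core)] = True  # padding is already pure noise
            if config.errors_only_in_overlap:
                lo, hi = _overlap_window(frag_len, L)
                keep = np.zeros(L, dtype=bool)
                keep[lo:hi] = True
                err_mask &= keep
            if not config.error_free:
                u = rng.random(L)
                shift = rng.integers(1, 4, size=L, dtype=np.int8)
                hit = err_mask & (u < 10.0 ** (-quals / 10.0))
                codes = np.where(hit, (codes + shift) % 4, codes).astype(np.int8)
            mates.append(Read(id=f"sim:{pid}", bases=_decode(codes), quals=quals))

        pairs.append(ReadPair(mates[0], mates[1]))
        truths.append(
            SimTruth(
                pair_id=pid,
                ref_id=f"ref{ref_idx}",
                fragment_start=start,
                fragment_length=frag_len,
                mergeable=(not force_no_overlap) and frag_len < 2 * L,
                fragment=_decode(frag),
            )
        )
    return pairs, truths


def simulate_dataset(config: SimConfig) -> tuple[list[ReadPair], list[SimTruth]]:
    """Simulate read pairs with fragment lengths ~ Normal(mean, sd), clamped
    to [1, ref_length].  Fully reproducible from ``config.seed``."""
    return _simulate(config, force_no_overlap=False)


def simulate_no_overlap_dataset(config: SimConfig) -> tuple[list[ReadPair], list[SimTruth]]:
    """Simulate pairs whose fragments are at least twice the read length, so
    the mates share no true sequence; every truth record is unmergeable."""
    return _simulate(config, force_no_overlap=True)


TRUTH_COLUMNS = ("pair_id", "ref_id", "fragment_start", "fragment_length", "mergeable")


def write_truth_table(truths: Iterable[SimTruth], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for t in truths:
            writer.writerow([t.pair_id, t.ref_id, t.fragment_start, t.fragment_length,
                             int(t.mergeable)])


def read_truth_table(path: str | Path) -> list[SimTruth]:
    """Read a truth TSV back (fragment sequences are not stored on disk)."""
    out = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            out.append(
                SimTruth(
                    pair_id=int(row["pair_id"]),
                    ref_id=row["ref_id"],
                    fragment_start=int(row["fragment_start"]),
                    fragment_length=int(row["fragment_length"]),
                    mergeable=bool(int(row["mergeable"])),
                    fragment="",
                )
            )
    return out


def simulate_to_files(
    config: SimConfig,
    forward_path: str | Path,
    reverse_path: str | Path,
    truth_path: str | Path,
    no_overlap: bool = False,
    encoding: QualityEncoding = QualityEncoding(),
) -> int:
    """Write forward/reverse FASTQ plus the truth TSV; returns the pair count."""
    pairs, truths = _simulate(config, force_no_overlap=no_overlap)
    write_fastq((p.forward for p in pairs), forward_path, encoding)
    write_fastq((p.reverse for p in pairs), reverse_path, encoding)
    write_truth_table(truths, truth_path)
    return len(pairs)


@dataclass(frozen=True)
class SimMetrics:
    """Benchmark-style metrics row: merged and correct counts, correct
    percentage of all pairs, and the false-positive rate in percent."""

    n_pairs: int
    n_merged: int
    n_correct: int
    correct_pct: float
    fpr_pct: float

    def __str__(self) -> str:
        return (
            f"pairs={self.n_pairs} merged={self.n_merged} correct={self.n_correct} "
            f"correct%={self.correct_pct:.2f} FPR%={self.fpr_pct:.2f}"
        )


def evaluate_outcomes(
    outcomes: Sequence[tuple[str, Optional[int]]], truths: Sequence[SimTruth]
) -> SimMetrics:
    """Score (status, merged_length) outcomes against the truth table.

    A mergeable pair is correct when it merged at exactly the true
    fragment length; an unmergeable pair is correct when it did not
    merge.  The FPR is incorrect merges over merged reads when the set
    contains mergeable pairs, and merged reads over all pairs for a pure
    no-overlap set (0/0 counts as 0).
    """
    if len(outcomes) != len(truths):
        raise ValueError(f"{len(outcomes)} outcomes but {len(truths)} truth records")
    n = len(truths)
    merged = correct = bad_merged = 0
    any_mergeable = False
    for (status, mlen), truth in zip(outcomes, truths):
        any_mergeable |= truth.mergeable
        is_merged = status == "merged"
        merged += is_merged
        ok = (
            (is_merged and mlen == truth.fragment_length)
            if truth.mergeable
            else not is_merged
        )
        correct += ok
        bad_merged += is_merged and not (truth.mergeable and mlen == truth.fragment_length)
    if any_mergeable:
        fpr = 100.0 * bad_merged / merged if merged else 0.0
    else:
        fpr = 100.0 * merged / n if n else 0.0
    return SimMetrics(
        n_pairs=n,
        n_merged=merged,
        n_correct=correct,
        correct_pct=100.0 * correct / n if n else 0.0,
        fpr_pct=fpr,
    )


def evaluate(results: Sequence[MergeResult], truths: Sequence[SimTruth]) -> SimMetrics:
    """Score full merge results against the truth table (see evaluate_outcomes)."""
    outcomes = [
        (r.status, len(r.merged) if r.merged is not None else None) for r in results
    ]
    return evaluate_outcomes(outcomes, truths)
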