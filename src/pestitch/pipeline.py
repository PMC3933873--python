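"""End-to-end orchestration: stream pairs, merge, test, filter, write.

Pairs are processed in fixed-size chunks so that the resident set is
bounded by two chunks regardless of input size.  With ``workers > 1``
each chunk is split across a process pool and reassembled in input
order, so the four output files are byte-identical for any worker
count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from multiprocessing import Pool
from typing import Callable, Iterable, Iterator, Optional

from .consensus import merge_pair
from .filters import FilterConfig, classify
from .io import (
    MergeOutputWriter,
    QualityEncoding,
    Read,
    ReadPair,
    read_paired_fastq,
)
from .scoring import (
    BaseFrequencies,
    ScoringParams,
    ScoringTables,
    estimate_base_frequencies,
)
from .significance import TestConfig

#: per-pair record sent back from workers: status, merged length (or None),
#: and the classified (category, record) outputs to write
PairOutput = tuple[str, Optional[int], list[tuple[str, Read]]]


@dataclass(frozen=True)
class RunConfig:
    forward_path: str
    reverse_path: str
    output_prefix: str
    encoding: QualityEncoding = field(default_factory=QualityEncoding)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    test: TestConfig = field(default_factory=TestConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    min_overlap: int = 10
    uniform_freqs: bool = False
    quality_cap: Optional[int] = None
    chunk_size: int = 5000
    workers: int = 1
    gzip_output: bool = False

    def __post_init__(self) -> None:
        if self.chunk_size < 1 or self.workers < 1:
            raise ValueError("chunk_size and workers must be >= 1")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class RunSummary:
    n_pairs: int = 0
    n_merged: int = 0
    n_unmerged: int = 0
    counts: dict = field(default_factory=lambda: {
        "assembled": 0, "forward": 0, "reverse": 0, "discarded": 0,
    })
    base_frequencies: Optional[BaseFrequencies] = None

    def as_key_values(self) -> str:
        parts = [f"pairs={self.n_pairs}", f"merged_pairs={self.n_merged}",
                 f"unmerged_pairs={self.n_unmerged}"]
        parts += [f"{k}_records={v}" for k, v in self.counts.items()]
        return " ".join(parts)


_WORKER: dict = {}


def _init_worker(params, freqs, test, filters, encoding, min_overlap, quality_cap) -> None:
    _WORKER.update(
        params=params, freqs=freqs, test=test, filters=filters, encoding=encoding,
        min_overlap=min_overlap, quality_cap=quality_cap,
        tables=ScoringTables(params, freqs),
    )


def _process_chunk(chunk: list[ReadPair]) -> list[PairOutput]:
    w = _WORKER
    out: list[PairOutput] = []
    for pair in chunk:
        result = merge_pair(
            pair, params=w["params"], freqs=w["freqs"], test=w["test"],
            encoding=w["encoding"], min_overlap=w["min_overlap"],
            tables=w["tables"], quality_cap=w["quality_cap"],
        )
        records = classify(result, pair, w["filters"])
        out.append(
            (result.status, len(result.merged) if result.merged else None, records)
        )
    return out


def _chunked(pairs: Iterable[ReadPair], size: int) -> Iterator[list[ReadPair]]:
    it = iter(pairs)
    while chunk := list(itertools.islice(it, size)):
        yield chunk


def _split(chunk: list, parts: int) -> list[list]:
    k, m = divmod(len(chunk), parts)
    bounds = [i * k + min(i, m) for i in range(parts + 1)]
    return [chunk[bounds[i] : bounds[i + 1]] for i in range(parts) if bounds[i] < bounds[i + 1]]


def run(
    config: RunConfig,
    collect_outcomes: bool = False,
    progress: Optional[Callable[[int], None]] = None,
) -> tuple[RunSummary, Optional[list[tuple[str, Optional[int]]]]]:
    """Execute the merge pipeline.

    Returns the run summary and, when ``collect_outcomes`` is set, the
    per-pair (status, merged_length) list in input order (used by the
    evaluation harness).  ``progress``, if given, receives each processed
    chunk's size — the instrumentation hook for the bounded-memory
    contract (at most one chunk is resident per call).
    """
    if config.uniform_freqs:
        freqs = BaseFrequencies.uniform()
    else:
        freqs = estimate_base_frequencies(
            read_paired_fastq(config.forward_path, config.reverse_path, config.encoding)
        )

    summary = RunSummary(base_frequencies=freqs)
    outcomes: Optional[list] = [] if collect_outcomes else None
    init_args = (
        config.scoring, freqs, config.test, config.filters, config.encoding,
        config.min_overlap, config.quality_cap,
    )
    pairs = read_paired_fastq(config.forward_path, config.reverse_path, config.encoding)

    def handle(results: list[PairOutput]) -> None:
        for status, merged_len, records in results:
            summary.n_pairs += 1
            if status == "merged":
                summary.n_merged += 1
            else:
                summary.n_unmerged += 1
            if outcomes is not None:
                outcomes.append((status, merged_len))
            for category, record in records:
                writer.write(category, record)
        if progress is not None:
            progress(len(results))

    with MergeOutputWriter(
        config.output_prefix, config.encoding, gzip_output=config.gzip_output
    ) as writer:
        if config.workers == 1:
            _init_worker(*init_args)
            for chunk in _chunked(pairs, config.chunk_size):
                handle(_process_chunk(chunk))
        else:
            with Pool(config.workers, initializer=_init_worker, initargs=init_args) as pool:
                for chunk in _chunked(pairs, config.chunk_size):
                    parts = pool.map(_process_chunk, _split(chunk, config.workers))
                    handle([item for part in parts for item in part])
        summary.counts = dict(writer.counts)
    return summary, outcomes
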