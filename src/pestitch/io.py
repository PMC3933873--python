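"""Synchronized paired-FASTQ input and four-way FASTQ output.

Reads are paired strictly by position: record *i* of the forward file is
mated with record *i* of the reverse file, exactly as the instrument
software emits them.  Read identifiers are never parsed or compared.
Gzip-compressed files are handled transparently by extension.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, NamedTuple

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class QualityEncoding:
    """ASCII offset and cap for Phred quality scores in FASTQ.

    ``ascii_offset`` is 33 for Sanger/modern Illumina data and 64 for
    early CASAVA output.  ``max_quality`` is the largest encodable
    quality (the printable-ASCII ceiling for the offset).
    """

    ascii_offset: int = 33
    max_quality: int = 93

    def __post_init__(self) -> None:
        if self.ascii_offset not in (33, 64):
            raise ValueError(f"ascii_offset must be 33 or 64, got {self.ascii_offset}")
        if not 0 < self.max_quality <= 126 - self.ascii_offset:
            raise ValueError(
                f"max_quality {self.max_quality} not encodable at offset {self.ascii_offset}"
            )

    @classmethod
    def phred33(cls) -> "QualityEncoding":
        return cls(33, 93)

    @classmethod
    def phred64(cls) -> "QualityEncoding":
        return cls(64, 62)


@dataclass
class Read:
    """A sequence record: identifier, bases over {A,C,G,T,N}, Phred qualities."""

    id: str
    bases: str
    quals: np.ndarray  # integer Phred scores, same length as bases

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but {len(self.quals)} qualities"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Read):
            return NotImplemented
        return (
            self.id == other.id
            and self.bases == other.bases
            and np.array_equal(self.quals, other.quals)
        )


class ReadPair(NamedTuple):
    forward: Read
    reverse: Read


def _open_text(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _decode_record(
    title: str, seq: str, qual: str, encoding: QualityEncoding, index: int, path: str | Path
) -> Read:
    seq = seq.upper()
    if not _VALID_BASES.issuperset(seq):
        bad = sorted(set(seq) - _VALID_BASES)
        raise ValueError(f"{path}: record {index}: unexpected base symbol(s) {bad}")
    quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
    quals -= encoding.ascii_offset
    if len(quals) and quals.min() < 0:
        raise ValueError(
            f"{path}: record {index}: negative quality after decoding with offset "
            f"{encoding.ascii_offset}; the file may use a different Phred offset"
        )
    return Read(id=title.split()[0] if title else "", bases=seq, quals=quals)


def _iter_fastq(path: str | Path, encoding: QualityEncoding) -> Iterator[Read]:
    with _open_text(path, "r") as handle:
        index = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                yield _decode_record(title, seq, qual, encoding, index, path)
                index += 1
        except ValueError as err:
            if "record" in str(err):
                raise
            raise ValueError(f"{path}: malformed FASTQ at record {index}: {err}") from err


def read_paired_fastq(
    forward_path: str | Path,
    reverse_path: str | Path,
    encoding: QualityEncoding = QualityEncoding(),
) -> Iterator[ReadPair]:
    """Stream positionally matched read pairs from two FASTQ files.

    Raises ``ValueError`` if the files do not hold the same number of
    records, if a record is malformed, or if a decoded quality is
    negative (wrong Phred offset).
    """
    fwd = _iter_fastq(forward_path, encoding)
    rev = _iter_fastq(reverse_path, encoding)
    n_fwd = n_rev = 0
    while True:
        f = next(fwd, None)
        r = next(rev, None)
        if f is None and r is None:
            return
        if f is None or r is None:
            n_fwd += f is not None
            n_rev += r is not None
            # drain the longer file to report both totals
            for _ in fwd:
                n_fwd += 1
            for _ in rev:
                n_rev += 1
            raise ValueError(
                f"record-count mismatch: {forward_path} has {n_fwd} records, "
                f"{reverse_path} has {n_rev}"
            )
        n_fwd += 1
        n_rev += 1
        yield ReadPair(f, r)


def _format_record(read: Read, encoding: QualityEncoding) -> str:
    quals = read.quals
    if len(quals) and (quals.min() < 0 or quals.max() > encoding.max_quality):
        raise ValueError(
            f"read {read.id!r}: quality outside [0, {encoding.max_quality}]; cap before writing"
        )
    qual_str = (quals.astype(np.uint8) + encoding.ascii_offset).tobytes().decode("ascii")
    return f"@{read.id}\n{read.bases}\n+\n{qual_str}\n"


def write_fastq(
    records: Iterable[Read],
    path: str | Path,
    encoding: QualityEncoding = QualityEncoding(),
) -> int:
    """Write records as 4-line FASTQ (gzipped if the path ends in .gz).

    Returns the number of records written.  Round-trips with
    :func:`read_paired_fastq`'s decoder for in-range qualities.
    """
    n = 0
    with _open_text(path, "w") as handle:
        for read in records:
            handle.write(_format_record(read, encoding))
            n += 1
    return n


#: suffixes of the four output files, keyed by category
OUTPUT_SUFFIXES = {
    "assembled": ".assembled.fastq",
    "forward": ".unassembled.forward.fastq",
    "reverse": ".unassembled.reverse.fastq",
    "discarded": ".discarded.fastq",
}


@dataclass
class MergeOutputWriter:
    """Four-way FASTQ writer for merged / unmerged-forward / unmerged-reverse /
    discarded reads, named ``<prefix>.<category>.fastq``."""

    prefix: str
    encoding: QualityEncoding = field(default_factory=QualityEncoding)
    gzip_output: bool = False

    def __post_init__(self) -> None:
        ext = ".gz" if self.gzip_output else ""
        self.paths = {
            cat: Path(str(self.prefix) + suffix + ext) for cat, suffix in OUTPUT_SUFFIXES.items()
        }
        self._handles = {cat: _open_text(p, "w") for cat, p in self.paths.items()}
        self.counts = {cat: 0 for cat in OUTPUT_SUFFIXES}

    def write(self, category: str, read: Read) -> None:
        self._handles[category].write(_format_record(read, self.encoding))
        self.counts[category] += 1

    def close(self) -> None:
        for handle in self._handles.values():
            handle.close()

    def __enter__(self) -> "MergeOutputWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
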