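"""FASTQ/FASTA/TSV readers and writers.

All sequences are normalised to the DNA alphabet on ingest (U -> T,
lower -> upper); internal comparisons are DNA-only.  FASTQ qualities are
Phred+33.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

_DNA_NORM = str.maketrans("uU", "TT")

MAX_PHRED = 60


class FastqFormatError(ValueError):
    """Malformed FASTQ record (reported with its 0-based record index)."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U to T."""
    return seq.translate(_DNA_NORM).upper()


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id, DNA sequence over {A,C,G,T,N}, Phred scores."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if any(q < 0 or q > MAX_PHRED for q in self.qualities):
            raise ValueError(f"read {self.read_id!r}: Phred score outside [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def parse_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a (possibly gzipped) 4-line FASTQ file.

    U is normalised to T; record order is preserved.  A record whose
    sequence and quality strings differ in length raises
    :class:`FastqFormatError` naming the record index.
    """
    with _open_text(path) as handle:
        index = 0
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(f"malformed FASTQ record at index {index}: {exc}") from exc
            quals = tuple(ord(c) - 33 for c in qual)
            try:
                yield ReadRecord(title.split()[0], normalize_sequence(seq), quals)
            except ValueError as exc:
                raise FastqFormatError(f"malformed FASTQ record at index {index}: {exc}") from exc
            index += 1


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write records as Phred+33 FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as handle:
        for rec in records:
            qual = "".join(chr(q + 33) for q in rec.qualities)
            handle.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


def parse_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: DNA sequence} map.

    Duplicate ids raise; sequences are U->T normalised.
    """
    from Bio import SeqIO

    out: dict[str, str] = {}
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate reference id {rec.id!r} in {path}")
            out[rec.id] = normalize_sequence(str(rec.seq))
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


@dataclass
class FilterReport:
    """Per-reason read accounting for the preprocessing stage."""

    n_input: int = 0
    n_pass: int = 0
    n_fail_quality: int = 0
    n_fail_short: int = 0
    n_fail_long: int = 0
    n_untrimmed: int = 0
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_pass": self.n_pass,
            "n_fail_quality": self.n_fail_quality,
            "n_fail_short": self.n_fail_short,
            "n_fail_long": self.n_fail_long,
            "n_untrimmed": self.n_untrimmed,
            **self.extra,
        }
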