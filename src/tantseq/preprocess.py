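"""Adapter trimming, quality/length filtering and chemistry demultiplexing.

Reads have the layout insert + 6-nt chemistry barcode + constant 3'
adapter.  Trimming removes the adapter and everything downstream of it but
keeps the barcode; the quality and length filters (mean Phred >= 30,
21-46 nt) apply to the barcode-attached read; demultiplexing then matches
the terminal 6-mer exactly against the two sublibrary barcodes and strips
it, leaving a 15-40 nt insert.  Exact barcode matching guarantees zero
cross-assignment between the 3'-OH and 3'-cP sublibraries (the two
barcodes differ at every position).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from tantseq.config import BARCODE_LENGTH, PipelineConfig
from tantseq.io import FilterReport, ReadRecord


@dataclass(frozen=True)
class DemuxedRead:
    """Barcode-stripped insert routed to a chemistry sublibrary."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    chemistry: str  # "OH" or "cP"
    barcode_observed: str

    def __len__(self) -> int:
        return len(self.sequence)


def trim_adapter(
    read: ReadRecord, adapter: str, min_overlap: int = 8, max_mismatch: int = 1
) -> tuple[ReadRecord, bool]:
    """Remove the 3' adapter (and anything past it), keeping the barcode.

    The longest read suffix matching a prefix of the adapter wins: scanning
    candidate start positions left to right, the first position where the
    overlapping region (>= min_overlap nt) has at most `max_mismatch`
    mismatches is cut.  Returns (read, trimmed_flag); untrimmed reads pass
    through unchanged with the flag False.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        region_len = min(n - i, len(adapter))
        if region_len < min_overlap:
            break
        mismatches = 0
        ok = True
        for a, b in zip(seq[i : i + region_len], adapter[:region_len]):
            if a != b:
                mismatches += 1
                if mismatches > max_mismatch:
                    ok = False
                    break
        if ok:
            return ReadRecord(read.read_id, seq[:i], read.qualities[:i]), True
    return read, False


def _passes_quality(read: ReadRecord, config: PipelineConfig) -> bool:
    if not read.qualities:
        return False
    if config.quality_rule == "mean":
        return read.mean_quality >= config.phred_threshold
    low = sum(1 for q in read.qualities if q < config.phred_threshold)
    return low / len(read.qualities) <= config.max_low_quality_fraction


def quality_length_filter(
    reads: Iterable[ReadRecord], config: PipelineConfig
) -> tuple[list[ReadRecord], FilterReport]:
    """Keep reads with passing quality and post-trim length in [min_len, max_len].

    The length window (default 21-46 nt) is applied with the barcode still
    attached.  The report counts one failure reason per read (quality
    checked first, then length).
    """
    kept: list[ReadRecord] = []
    report = FilterReport()
    for read in reads:
        report.n_input += 1
        if not _passes_quality(read, config):
            report.n_fail_quality += 1
        elif len(read) < config.min_len:
            report.n_fail_short += 1
        elif len(read) > config.max_len:
            report.n_fail_long += 1
        else:
            report.n_pass += 1
            kept.append(read)
    return kept, report


def demultiplex(
    reads: Iterable[ReadRecord], config: PipelineConfig
) -> tuple[list[DemuxedRead], list[DemuxedRead], list[ReadRecord]]:
    """Route reads into (OH sublibrary, cP sublibrary, unassigned).

    The terminal 6-mer is compared exactly against barcode_oh, then
    barcode_cp; on a match the barcode is stripped.  |OH| + |cP| +
    |unassigned| always equals the input count.
    """
    oh: list[DemuxedRead] = []
    cp: list[DemuxedRead] = []
    unassigned: list[ReadRecord] = []
    for read in reads:
        barcode = read.sequence[-BARCODE_LENGTH:]
        if len(read) > BARCODE_LENGTH and barcode == config.barcode_oh:
            bucket, chem = oh, "OH"
        elif len(read) > BARCODE_LENGTH and barcode == config.barcode_cp:
            bucket, chem = cp, "cP"
        else:
            unassigned.append(read)
            continue
        bucket.append(
            DemuxedRead(
                read_id=read.read_id,
                sequence=read.sequence[:-BARCODE_LENGTH],
                qualities=read.qualities[:-BARCODE_LENGTH],
                chemistry=chem,
                barcode_observed=barcode,
            )
        )
    return oh, cp, unassigned


def preprocess_reads(
    reads: Iterable[ReadRecord], config: PipelineConfig
) -> tuple[list[DemuxedRead], list[DemuxedRead], list[ReadRecord], FilterReport]:
    """trim -> filter -> demultiplex in one pass; returns (OH, cP, unassigned, report)."""
    trimmed: list[ReadRecord] = []
    n_untrimmed = 0
    for read in reads:
        t, flag = trim_adapter(read, config.adapter, config.min_adapter_overlap)
        if not flag:
            n_untrimmed += 1
        trimmed.append(t)
    kept, report = quality_length_filter(trimmed, config)
    report.n_untrimmed = n_untrimmed
    oh, cp, unassigned = demultiplex(kept, config)
    report.extra["n_oh"] = len(oh)
    report.extra["n_cp"] = len(cp)
    report.extra["n_unassigned"] = len(unassigned)
    return oh, cp, unassigned, report
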