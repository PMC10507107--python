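"""Two-round sequential tiered alignment and biotype assignment.

A read is assigned by walking the reference tiers in priority order twice:
round 1 accepts only perfect (0-edit) placements; reads left unassigned are
walked again in round 2 with a relaxed budget (mismatches + gaps <= 2,
each gapped position costing 1).  The first tier with a hit wins, so a
perfect hit to a low-priority tier beats an inexact hit to a high-priority
tier.  Reads unmapped after both rounds are discarded downstream.

The search itself is a bounded semi-global scan: the full query must lie
inside a reference window, cost = substitutions + gap positions, minimised
over all windows (and both strands for genome/repeat tiers).  Ties break
deterministically by (fewer edits, lexicographically smaller reference id,
leftmost start, '+' strand before '-', smallest end).  'N' never matches
any base.  Candidate windows come from an edit-distance pigeonhole: any
placement within k edits contains at least one of k+1 query segments
exactly, so exact segment occurrences seed the dynamic programming.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from tantseq.config import PipelineConfig
from tantseq.references import ReferenceTier

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Simplified-nomenclature biotype prefixes ({prefix}-{rank}-{mod}).
SIMPLE_NAME_PREFIX = {
    "srRNA": "srR",
    "tsRNA": "tsR",
    "snRNA": "snR",
    "snoRNA": "snoR",
    "sinRNA": "sinR",
    "slncRNA": "slncR",
    "sgmRNA": "sgmR",
    "smRNA": "smR",
    "srpRNA": "srpR",
    "smcRNA": "smcR",
    "piRNA": "piR",
    "miRNA": "miR",
    "spikein": "spike",
}

TSRNA_SUBTYPES = ("5p", "cca3p", "cc3p", "internal", "not_applicable")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Alignment:
    """Semi-global placement of a query inside a reference (1-based, inclusive)."""

    reference_id: str
    tier_name: str
    start: int
    end: int
    strand: str
    edits: int
    round: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("alignment start must be <= end")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class ClassifiedRead:
    read_id: str
    sequence: str
    chemistry: str
    biotype_label: str
    alignment: Alignment
    tsrna_subtype: str = "not_applicable"


def _edit_rows(query: str, text: str) -> list[list[int]]:
    """Full Levenshtein DP of `query` (rows) against `text` (cols);
    'N' matches nothing, including 'N'."""
    m, n = len(query), len(text)
    prev = list(range(n + 1))
    rows = [prev]
    for i in range(1, m + 1):
        qc = query[i - 1]
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            tc = text[j - 1]
            sub = 0 if (qc == tc and qc != "N") else 1
            cur[j] = min(prev[j - 1] + sub, prev[j] + 1, cur[j - 1] + 1)
        rows.append(cur)
        prev = cur
    return rows


def _final_row(query: str, text: str) -> list[int]:
    return _edit_rows(query, text)[-1]


def _find_all(text: str, pattern: str) -> Iterable[int]:
    pos = text.find(pattern)
    while pos != -1:
        yield pos
        pos = text.find(pattern, pos + 1)


def _candidate_starts(query: str, ref: str, k: int) -> set[int]:
    """Pigeonhole seeding: starts of windows that could hold the query
    within k edits."""
    m, n = len(query), len(ref)
    starts: set[int] = set()
    if m - k > n:
        return starts
    if k == 0:
        return set(_find_all(ref, query)) if "N" not in query else starts
    # split into k+1 contiguous parts; one must occur exactly
    n_parts = k + 1
    bounds = [round(i * m / n_parts) for i in range(n_parts + 1)]
    hi = n - (m - k)
    for p in range(n_parts):
        o, e = bounds[p], bounds[p + 1]
        part = query[o:e]
        if not part or "N" in part:
            continue
        for occ in _find_all(ref, part):
            anchor = occ - o
            for d in range(-k, k + 1):
                s = anchor + d
                if 0 <= s <= hi:
                    starts.add(s)
    return starts


def _best_in_sequence(query: str, ref: str, max_edits: int) -> tuple[int, int, int] | None:
    """Minimal-cost window placement of `query` in `ref`.

    Returns (edits, start0, end0) minimising (edits, start0, end0), or None
    if no window is within max_edits.
    """
    m, n = len(query), len(ref)
    best: tuple[int, int, int] | None = None
    for s in sorted(_candidate_starts(query, ref, max_edits)):
        text = ref[s : s + m + max_edits]
        row = _final_row(query, text)
        for L in range(max(1, m - max_edits), min(len(text), m + max_edits) + 1):
            cost = row[L]
            if cost > max_edits:
                continue
            cand = (cost, s, s + L - 1)
            if best is None or cand < best:
                best = cand
    return best


def align_to_tier(query: str, tier: ReferenceTier, max_edits: int) -> Alignment | None:
    """Best placement of `query` in one tier, or None.

    References are scanned in lexicographic id order; tie-breaking follows
    (edits, reference_id, leftmost 1-based start on the reference, '+'
    before '-', smallest end).  Minus-strand hits (both-strand tiers only)
    are found by scanning the reverse complement and reported in forward
    reference coordinates.
    """
    best_key: tuple | None = None
    best_aln: Alignment | None = None
    for ref_id in sorted(tier.sequences):
        ref = tier.sequences[ref_id]
        strands = ("+", "-") if tier.search_both_strands else ("+",)
        for strand in strands:
            target = ref if strand == "+" else reverse_complement(ref)
            hit = _best_in_sequence(query, target, max_edits)
            if hit is None:
                continue
            cost, s0, e0 = hit
            if strand == "-":
                n = len(ref)
                s0, e0 = n - 1 - e0, n - 1 - s0
            key = (cost, ref_id, s0, 0 if strand == "+" else 1, e0)
            if best_key is None or key < best_key:
                best_key = key
                best_aln = Alignment(
                    reference_id=ref_id,
                    tier_name=tier.tier_name,
                    start=s0 + 1,
                    end=e0 + 1,
                    strand=strand,
                    edits=cost,
                )
    return best_aln


def classify_read(
    query: str, registry: Sequence[ReferenceTier], max_edits: int = 2
) -> tuple[str, Alignment] | None:
    """Two-round priority walk; returns (biotype_label, alignment) or None.

    Round 1 accepts only exact placements, walking every tier in priority
    order; round 2 repeats the walk allowing up to `max_edits`.  The first
    tier with an acceptable hit wins.
    """
    for tier in registry:
        aln = align_to_tier(query, tier, 0)
        if aln is not None:
            return tier.biotype_label, replace(aln, round=1)
    if max_edits > 0:
        for tier in registry:
            aln = align_to_tier(query, tier, max_edits)
            if aln is not None:
                return tier.biotype_label, replace(aln, round=2)
    return None


def subclassify_tsrna(alignment: Alignment, query: str, precursor_with_cca: str,
                      biotype_label: str = "tsRNA") -> str:
    """tRNA-fragment subtype on the CCA-appended precursor.

    5' fragments (containing the precursor 5' end) take precedence over the
    3' conditions for full-length placements.
    """
    if biotype_label != "tsRNA":
        raise ValueError(f"subclassify_tsrna requires a tsRNA alignment, got {biotype_label!r}")
    n = len(precursor_with_cca)
    if alignment.end > n:
        raise ValueError("alignment extends past the precursor")
    if alignment.start == 1:
        return "5p"
    if alignment.end == n and query.endswith("CCA"):
        return "cca3p"
    if alignment.end == n - 1 and query.endswith("CC"):
        return "cc3p"
    return "internal"


class ReadClassifier:
    """Registry-bound classifier with per-sequence caching."""

    def __init__(self, registry: Sequence[ReferenceTier], config: PipelineConfig | None = None):
        self.registry = list(registry)
        self.max_edits = config.max_edits if config is not None else 2
        self._precursors = {
            tier.tier_name: tier.sequences for tier in self.registry
        }
        self._biotype_by_tier = {t.tier_name: t.biotype_label for t in self.registry}
        self._cache: dict[str, tuple[str, Alignment, str] | None] = {}

    def classify_sequence(self, sequence: str) -> tuple[str, Alignment, str] | None:
        """(biotype, alignment, tsrna_subtype) for one insert sequence."""
        if sequence in self._cache:
            return self._cache[sequence]
        hit = classify_read(sequence, self.registry, self.max_edits)
        result = None
        if hit is not None:
            biotype, aln = hit
            subtype = "not_applicable"
            if biotype == "tsRNA":
                precursor = self._precursors[aln.tier_name][aln.reference_id]
                subtype = subclassify_tsrna(aln, sequence, precursor, biotype)
            result = (biotype, aln, subtype)
        self._cache[sequence] = result
        return result

    def classify_reads(self, reads, chemistry: str) -> tuple[list[ClassifiedRead], int]:
        """Classify demultiplexed inserts; returns (classified, n_unmapped)."""
        out: list[ClassifiedRead] = []
        n_unmapped = 0
        for read in reads:
            res = self.classify_sequence(read.sequence)
            if res is None:
                n_unmapped += 1
                continue
            biotype, aln, subtype = res
            out.append(
                ClassifiedRead(
                    read_id=read.read_id,
                    sequence=read.sequence,
                    chemistry=chemistry,
                    biotype_label=biotype,
                    alignment=aln,
                    tsrna_subtype=subtype,
                )
            )
        return out, n_unmapped


def apply_overrides(
    classified: Iterable[ClassifiedRead],
    override_table: Mapping[str, str],
) -> tuple[list[ClassifiedRead], list[dict]]:
    """Re-label biotypes by exact insert sequence or by reference id.

    Mirrors manual curation of known misassignments (e.g. snoRNA fragments
    caught by the repeat tier).  Alignments are untouched; every change is
    recorded in an audit log.
    """
    from tantseq.references import BIOTYPE_LABELS

    for key, biotype in override_table.items():
        if biotype not in BIOTYPE_LABELS:
            raise ValueError(f"override target {biotype!r} is not a known biotype")
    out: list[ClassifiedRead] = []
    audit: list[dict] = []
    for rec in classified:
        new_biotype = override_table.get(rec.sequence) or override_table.get(
            rec.alignment.reference_id
        )
        if new_biotype and new_biotype != rec.biotype_label:
            audit.append(
                {
                    "read_id": rec.read_id,
                    "sequence": rec.sequence,
                    "reference_id": rec.alignment.reference_id,
                    "old_biotype": rec.biotype_label,
                    "new_biotype": new_biotype,
                }
            )
            rec = replace(rec, biotype_label=new_biotype,
                          tsrna_subtype="not_applicable" if new_biotype != "tsRNA" else rec.tsrna_subtype)
        out.append(rec)
    return out, audit


def aggregate_species(
    classified_by_sample: Mapping[str, Sequence[ClassifiedRead]],
) -> pd.DataFrame:
    """Collapse classified reads into unique (sequence, chemistry) species.

    Returns one row per species with per-sample raw counts and their
    arithmetic mean (`mean_reads`); row order is deterministic regardless
    of read order.
    """
    samples = list(classified_by_sample)
    species: dict[tuple[str, str], dict] = {}
    for sample, reads in classified_by_sample.items():
        for rec in reads:
            key = (rec.sequence, rec.chemistry)
            row = species.get(key)
            if row is None:
                row = {
                    "sequence": rec.sequence,
                    "chemistry": rec.chemistry,
                    "biotype": rec.biotype_label,
                    "tsrna_subtype": rec.tsrna_subtype,
                    "reference_id": rec.alignment.reference_id,
                    "tier": rec.alignment.tier_name,
                    "start": rec.alignment.start,
                    "end": rec.alignment.end,
                    "strand": rec.alignment.strand,
                    "length": len(rec.sequence),
                    **{f"count_{s}": 0 for s in samples},
                }
                species[key] = row
            row[f"count_{sample}"] += 1
    df = pd.DataFrame(sorted(species.values(), key=lambda r: (r["biotype"], r["chemistry"], r["sequence"])))
    if df.empty:
        cols = ["sequence", "chemistry", "biotype", "tsrna_subtype", "reference_id",
                "tier", "start", "end", "strand", "length"] + [f"count_{s}" for s in samples]
        df = pd.DataFrame(columns=cols)
    count_cols = [f"count_{s}" for s in samples]
    df["mean_reads"] = df[count_cols].mean(axis=1) if count_cols else 0.0
    return df.reset_index(drop=True)


def assign_names(species: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Attach the dual nomenclature to an aggregated species table.

    full_name = {biotype}|{reference_id}|{start}|{length}|{mod}; the
    simplified name {prefix}-{rank}-{mod} ranks species by mean_reads
    (descending, ties by lexicographic sequence) within each (biotype,
    chemistry) group and is only assigned when mean_reads strictly exceeds
    the naming threshold (default 2).
    """
    threshold = config.naming_min_mean_reads if config is not None else 2.0
    df = species.copy()
    if df.empty:
        df["full_name"] = pd.Series(dtype=object)
        df["simple_name"] = pd.Series(dtype=object)
        return df
    df["full_name"] = [
        f"{r.biotype}|{r.reference_id}|{r.start}|{r.length}|{r.chemistry}"
        for r in df.itertuples()
    ]
    simple = [None] * len(df)
    for (_, _), grp in df.groupby(["biotype", "chemistry"], sort=False):
        order = grp.sort_values(["mean_reads", "sequence"], ascending=[False, True], kind="mergesort")
        for rank, (idx, row) in enumerate(order.iterrows(), start=1):
            if row["mean_reads"] > threshold:
                prefix = SIMPLE_NAME_PREFIX[row["biotype"]]
                simple[df.index.get_loc(idx)] = f"{prefix}-{rank}-{row['chemistry']}"
    df["simple_name"] = simple
    return df
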