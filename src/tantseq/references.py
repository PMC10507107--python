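"""Reference tier registry for sequential (priority-ordered) mapping.

Reads are assigned to the first tier that accepts them, walking tiers in a
fixed priority order (spike-ins and rRNA first, genome last).  tRNA tiers
receive the post-transcriptional 3'-CCA on every sequence at load time
(genomic tRNA references are conventionally CCA-less); the appending is
unconditional and can be disabled per tier for users supplying mature
tRNAs that already carry it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from tantseq.config import PipelineConfig
from tantseq.io import normalize_sequence, parse_fasta

logger = logging.getLogger(__name__)

#: Closed set of small-RNA biotype labels.
BIOTYPE_LABELS = frozenset(
    {
        "spikein", "srRNA", "tsRNA", "miRNA", "piRNA", "snRNA", "snoRNA",
        "slncRNA", "smcRNA", "sinRNA", "smRNA", "srpRNA", "sgmRNA",
    }
)

#: Default tier-name -> biotype mapping (rRNA-derived -> srRNA, tRNA-derived
#: -> tsRNA, intron -> sinRNA, lncRNA -> slncRNA, genome -> sgmRNA, mature
#: mRNA incl. IG/TR/pseudogene/TEC -> smRNA, repeat -> srpRNA,
#: miscRNA -> smcRNA).
TIER_BIOTYPES = {
    "spikein": "spikein",
    "rRNA": "srRNA",
    "tRNA": "tsRNA",
    "mt-tRNA": "tsRNA",
    "miRNA": "miRNA",
    "piRNA": "piRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "lncRNA": "slncRNA",
    "miscRNA": "smcRNA",
    "intron": "sinRNA",
    "mRNA": "smRNA",
    "IG": "smRNA",
    "TR": "smRNA",
    "pseudogene": "smRNA",
    "TEC": "smRNA",
    "repeat": "srpRNA",
    "genome": "sgmRNA",
    "mt-genome": "sgmRNA",
}

#: Tiers whose reads may come from either genomic strand; transcript tiers
#: are searched sense-strand only (small RNAs are sense fragments of their
#: precursors).
BOTH_STRAND_TIERS = frozenset({"repeat", "genome", "mt-genome"})

#: Tiers that receive the 3'-CCA at load time.
TRNA_TIERS = frozenset({"tRNA", "mt-tRNA"})

#: The paper-style priority walk, for building registries by tier name.
DEFAULT_TIER_ORDER = (
    "spikein", "rRNA", "tRNA", "mt-tRNA", "miRNA", "piRNA", "snRNA",
    "snoRNA", "lncRNA", "miscRNA", "intron", "mRNA", "repeat", "genome",
)


def biotype_for_tier(tier_name: str) -> str:
    try:
        return TIER_BIOTYPES[tier_name]
    except KeyError:
        raise ValueError(f"no biotype mapping for tier {tier_name!r}") from None


@dataclass
class TierSpec:
    """How to build one tier: a name, a FASTA path or in-memory sequences."""

    tier_name: str
    path: str | Path | None = None
    sequences: dict[str, str] | None = None
    biotype_label: str | None = None
    append_cca: bool | None = None  # None -> inferred from tier name
    search_both_strands: bool | None = None


@dataclass
class ReferenceTier:
    tier_name: str
    biotype_label: str
    priority_rank: int
    sequences: dict[str, str] = field(default_factory=dict)
    search_both_strands: bool = False

    def __len__(self) -> int:
        return len(self.sequences)


def load_tier_registry(
    tier_specs: list[TierSpec],
    config: PipelineConfig | None = None,
) -> list[ReferenceTier]:
    """Build an ordered tier registry; list order is the mapping priority.

    tRNA-labelled tiers get "CCA" appended to every sequence exactly once —
    unconditionally, even if a sequence already ends in CCA (the builder
    does not second-guess the reference; disable per tier via
    ``append_cca=False``).  Duplicate reference ids within a tier raise;
    an empty tier is kept with a warning.
    """
    registry: list[ReferenceTier] = []
    for rank, spec in enumerate(tier_specs, start=1):
        if spec.sequences is not None:
            seqs = {}
            for name, seq in spec.sequences.items():
                if name in seqs:
                    raise ValueError(f"duplicate reference id {name!r} in tier {spec.tier_name}")
                seqs[name] = normalize_sequence(seq)
        elif spec.path is not None:
            seqs = parse_fasta(spec.path)
        else:
            seqs = {}

        append_cca = spec.append_cca
        if append_cca is None:
            append_cca = spec.tier_name in TRNA_TIERS
        if append_cca:
            seqs = {name: seq + "CCA" for name, seq in seqs.items()}

        both = spec.search_both_strands
        if both is None:
            both = spec.tier_name in BOTH_STRAND_TIERS

        label = spec.biotype_label or biotype_for_tier(spec.tier_name)
        if label not in BIOTYPE_LABELS:
            raise ValueError(f"unknown biotype label {label!r} for tier {spec.tier_name}")

        if not seqs:
            warnings.warn(f"tier {spec.tier_name!r} is empty", stacklevel=2)
        registry.append(
            ReferenceTier(
                tier_name=spec.tier_name,
                biotype_label=label,
                priority_rank=rank,
                sequences=seqs,
                search_both_strands=bool(both),
            )
        )
    return registry


def load_registry_manifest(path: str | Path, config: PipelineConfig | None = None) -> list[ReferenceTier]:
    """Read an ordered TSV manifest (tier_name, fasta_path[, biotype_label,
    append_cca, both_strands]) into a registry; paths are resolved relative
    to the manifest."""
    base = Path(path).parent
    specs: list[TierSpec] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            tier_name, fasta = parts[0], parts[1]
            label = parts[2] if len(parts) > 2 and parts[2] else None
            cca = None if len(parts) <= 3 or parts[3] == "" else parts[3].lower() in ("1", "true", "yes")
            both = None if len(parts) <= 4 or parts[4] == "" else parts[4].lower() in ("1", "true", "yes")
            specs.append(
                TierSpec(tier_name, path=base / fasta, biotype_label=label,
                         append_cca=cca, search_both_strands=both)
            )
    return load_tier_registry(specs, config)
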