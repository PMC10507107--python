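"""Chemistry-faithful synthetic data with known ground truth.

Emulates the dual-chemistry library scheme end to end: toy reference tiers,
small-RNA species drawn from them with a 3'-OH / 3'-P / 3'-cP chemistry
mix, a nine-member spike-in panel (three chemistries x three 10-fold
concentration steps: 8 / 0.8 / 0.08 nM), and raw reads laid out as
insert + chemistry barcode + constant 3' adapter.

Chemistry routing mirrors the bench protocol: 3'-OH inserts receive the
OH-barcoded adapter (T4 Rnl2), 3'-cP inserts the cP-barcoded adapter
(RtcB), and 3'-P inserts yield no reads at all — dephosphorylation exposes
a 3'-OH that periodate oxidation then blocks.  Expected read counts are
proportional to true molar abundance times the chemistry-specific ligation
efficiency, so the quantification stage's efficiency correction can be
validated by parameter recovery.  Endogenous cP species are cut with a
pyrimidine | purine junction bias at the 3' end, emulating the
ribonuclease cleavage signature that produces cyclic phosphates.

A companion generator inverts the TE-qPCR closed form to produce Ct
triples from known end fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from tantseq.config import PipelineConfig
from tantseq.io import ReadRecord, write_fasta, write_fastq
from tantseq.references import ReferenceTier, TierSpec, load_tier_registry
from tantseq.teqpcr import CENSOR_CT, CtTriple

CHEMISTRIES = ("OH", "P", "cP")

#: Relative spike-in concentrations (nM), 10-fold steps.
SPIKE_LEVELS = (8.0, 0.8, 0.08)

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

#: Toy tier sizes (name, n_references, reference length) in priority order.
DEFAULT_TOY_TIERS = (
    ("rRNA", 3, 400),
    ("tRNA", 6, 73),
    ("mt-tRNA", 2, 70),
    ("miRNA", 4, 65),
    ("piRNA", 3, 60),
    ("snRNA", 3, 150),
    ("snoRNA", 3, 120),
    ("lncRNA", 3, 300),
    ("miscRNA", 2, 100),
    ("intron", 3, 300),
    ("mRNA", 4, 400),
    ("repeat", 3, 200),
    ("genome", 2, 800),
)

#: Precursor tiers must be able to contain a full species plus flanks.
MIN_PRECURSOR_LEN = 60


@dataclass(frozen=True)
class TrueSpecies:
    """Ground-truth twin of an observed small-RNA species."""

    species_id: str
    sequence: str
    chemistry: str  # OH | P | cP
    source_tier: str
    source_ref: str
    start: int  # 1-based on the precursor
    true_abundance: float
    cp_junction_flagged: bool = False  # precursor had no pyrimidine|purine junction

    def __post_init__(self) -> None:
        if self.chemistry not in CHEMISTRIES:
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        if self.true_abundance <= 0:
            raise ValueError("true_abundance must be > 0")


@dataclass
class SpikeInPanel:
    """Nine synthetic controls: {OH, P, cP} x {8, 0.8, 0.08} nM."""

    species: list[TrueSpecies] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species and len(self.species) != 9:
            raise ValueError("spike-in panel must have exactly 9 members")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_spikein_panel(seed: int, length: int = 25) -> SpikeInPanel:
    """Generate the 3-chemistry x 3-level spike-in panel.

    Sequences are random (stand-ins for the proprietary bench oligos); the
    panel structure — chemistry and 10-fold concentration tiers — is what
    downstream checks rely on.
    """
    rng = np.random.default_rng(seed)
    species: list[TrueSpecies] = []
    sequences: dict[str, str] = {}
    for level in SPIKE_LEVELS:
        for chem in CHEMISTRIES:
            name = f"spike_{chem}_{level:g}nM"
            seq = _random_seq(rng, length)
            sequences[name] = seq
            species.append(
                TrueSpecies(
                    species_id=name,
                    sequence=seq,
                    chemistry=chem,
                    source_tier="spikein",
                    source_ref=name,
                    start=1,
                    true_abundance=level,
                )
            )
    return SpikeInPanel(species=species, sequences=sequences)


def build_toy_references(
    seed: int,
    tier_spec: Sequence[tuple[str, int, int]] = DEFAULT_TOY_TIERS,
    out_dir: str | Path | None = None,
    spikein_panel: SpikeInPanel | None = None,
) -> list[ReferenceTier]:
    """Random reference tiers in priority order, reproducible under seed.

    `tier_spec` lists (tier_name, n_references, length); precursor tiers
    shorter than 60 nt are rejected (a species must fit inside with room to
    spare).  When `out_dir` is given, one FASTA per tier is written (tRNA
    tiers pre-CCA, as genomic references would be).  A spike-in panel, if
    supplied, becomes the first tier.
    """
    rng = np.random.default_rng(seed)
    specs: list[TierSpec] = []
    if spikein_panel is not None:
        specs.append(TierSpec("spikein", sequences=spikein_panel.sequences))
    raw: dict[str, dict[str, str]] = {}
    for tier_name, n_refs, length in tier_spec:
        if length < MIN_PRECURSOR_LEN:
            raise ValueError(
                f"tier {tier_name!r}: reference length {length} < {MIN_PRECURSOR_LEN} nt"
            )
        seqs = {f"{tier_name}_{i + 1}": _random_seq(rng, length) for i in range(n_refs)}
        raw[tier_name] = seqs
        specs.append(TierSpec(tier_name, sequences=seqs))
    registry = load_tier_registry(specs)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if spikein_panel is not None:
            write_fasta(spikein_panel.sequences, out_dir / "spikeins.fasta")
        for tier_name, seqs in raw.items():
            write_fasta(seqs, out_dir / f"{tier_name}.fasta")
    return registry


def _cp_end_positions(ref: str, length_min: int) -> list[int]:
    """1-based end positions at pyrimidine|purine junctions with room for a
    species of at least `length_min` nt upstream."""
    ends = []
    for j in range(length_min, len(ref)):  # end j, next base j+1 (1-based)
        if ref[j - 1] in PYRIMIDINES and ref[j] in PURINES:
            ends.append(j)
    return ends


def sample_species(
    registry: Sequence[ReferenceTier],
    n_species: int,
    chemistry_mix: tuple[float, float, float] = (0.45, 0.10, 0.45),
    cp_motif_bias: float = 0.95,
    seed: int = 0,
    length_range: tuple[int, int] = (15, 30),
    abundance_sigma: float = 1.0,
    screen_collisions: bool = True,
    max_attempts: int = 50,
) -> list[TrueSpecies]:
    """Draw ground-truth species as substrings of the reference tiers.

    Chemistry follows `chemistry_mix` (OH, P, cP); lengths are uniform on
    `length_range`; molar abundances are log-normal.  A cP species ends at
    a pyrimidine|purine junction of its precursor with probability
    `cp_motif_bias` (falling back, flagged, when the precursor has no such
    junction).  With `screen_collisions` a species whose sequence occurs
    exactly in a higher-priority tier is redrawn, so the source tier is the
    classification truth.
    """
    if not math.isclose(sum(chemistry_mix), 1.0, abs_tol=1e-9):
        raise ValueError("chemistry_mix must sum to 1")
    if not (0 <= cp_motif_bias <= 1):
        raise ValueError("cp_motif_bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tiers = [t for t in registry if t.tier_name != "spikein" and len(t) > 0]
    if not tiers:
        raise ValueError("registry has no non-spike-in tiers to sample from")
    lo, hi = length_range

    def collides(seq: str, source_rank: int) -> bool:
        for tier in registry:
            if tier.priority_rank >= source_rank:
                return False
            for ref in tier.sequences.values():
                if seq in ref:
                    return True
        return False

    seen: set[tuple[str, str]] = set()
    out: list[TrueSpecies] = []
    while len(out) < n_species:
        chem = CHEMISTRIES[rng.choice(3, p=list(chemistry_mix))]
        for _ in range(max_attempts):
            tier = tiers[rng.integers(len(tiers))]
            ref_id = sorted(tier.sequences)[rng.integers(len(tier))]
            ref = tier.sequences[ref_id]
            length = int(rng.integers(lo, hi + 1))
            if length > len(ref):
                continue
            flagged = False
            if chem == "cP" and rng.random() < cp_motif_bias:
                ends = _cp_end_positions(ref, length)
                if ends:
                    end = int(ends[rng.integers(len(ends))])
                    start = end - length + 1
                else:
                    flagged = True
                    start = int(rng.integers(1, len(ref) - length + 2))
            else:
                start = int(rng.integers(1, len(ref) - length + 2))
            seq = ref[start - 1 : start - 1 + length]
            if (seq, chem) in seen:
                continue
            if screen_collisions and collides(seq, tier.priority_rank):
                continue
            seen.add((seq, chem))
            out.append(
                TrueSpecies(
                    species_id=f"sp{len(out):05d}",
                    sequence=seq,
                    chemistry=chem,
                    source_tier=tier.tier_name,
                    source_ref=ref_id,
                    start=start,
                    true_abundance=float(rng.lognormal(0.0, abundance_sigma)),
                    cp_junction_flagged=flagged,
                )
            )
            break
        else:
            raise RuntimeError("could not draw a collision-free species; enlarge the references")
    return out


def synthesize_reads(
    species: Sequence[TrueSpecies],
    depth: int,
    error_rate: float = 0.0,
    config: PipelineConfig | None = None,
    seed: int = 0,
    spikein_panel: SpikeInPanel | None = None,
    fastq_path: str | Path | None = None,
    truth_path: str | Path | None = None,
    bad_read_fraction: float = 0.02,
    good_quality: int = 37,
    bad_quality: int = 20,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Emit reads (insert + chemistry barcode + 3' adapter) and a truth table.

    Expected per-species read counts are proportional to true_abundance x
    ligation efficiency of the species' chemistry; 3'-P species have
    efficiency 0 (periodate blocking) and never produce reads.  Exactly
    `depth` reads are drawn (multinomial).  Substitution errors are applied
    at `error_rate` per base; a `bad_read_fraction` of reads get uniformly
    low qualities to exercise the quality filter, the rest Q37.
    """
    if config is None:
        config = PipelineConfig()
    rng = np.random.default_rng(seed)
    pool = list(species) + (spikein_panel.species if spikein_panel else [])
    barcodes = {"OH": config.barcode_oh, "cP": config.barcode_cp}
    effs = {"OH": config.ligation_eff_oh, "cP": config.ligation_eff_cp, "P": 0.0}

    weights = np.array([sp.true_abundance * effs[sp.chemistry] for sp in pool], dtype=float)
    truth_cols = ["read_id", "species_id", "chemistry", "tier", "ref", "start", "length"]
    if depth <= 0 or weights.sum() == 0:
        reads: list[ReadRecord] = []
        truth = pd.DataFrame(columns=truth_cols)
    else:
        counts = rng.multinomial(depth, weights / weights.sum())
        reads = []
        truth_rows = []
        bases = np.array(list("ACGT"))
        j = 0
        for sp, cnt in zip(pool, counts):
            if cnt == 0:
                continue
            template = sp.sequence + barcodes[sp.chemistry] + config.adapter
            for _ in range(int(cnt)):
                seq = template
                if error_rate > 0:
                    arr = np.array(list(seq))
                    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
                    for pos in hits:
                        choices = [b for b in "ACGT" if b != arr[pos]]
                        arr[pos] = choices[rng.integers(3)]
                    seq = "".join(arr)
                q = bad_quality if rng.random() < bad_read_fraction else good_quality
                read_id = f"read{j:07d}"
                reads.append(ReadRecord(read_id, seq, (q,) * len(seq)))
                truth_rows.append(
                    (read_id, sp.species_id, sp.chemistry, sp.source_tier,
                     sp.source_ref, sp.start, len(sp.sequence))
                )
                j += 1
        truth = pd.DataFrame(truth_rows, columns=truth_cols)

    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return reads, truth


def simulate_ct_triples(
    true_fractions: tuple[float, float, float],
    total_amount: float = 1.0,
    c0: float = 20.0,
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> list[CtTriple]:
    """Invert the TE-qPCR closed form: fractions -> Ct triples.

    Ct_X = c0 - log_eff(detectable_fraction_X * total_amount) + N(0, sd),
    with detectable fractions OH, OH+P and OH+P+cP of the total; a
    zero-template treatment is censored at Ct 40.  `true_fractions` are
    percentages (OH, P, cP) summing to 100.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    if total_amount <= 0:
        raise ValueError("total_amount must be > 0")
    f_oh, f_p, f_cp = (f / 100.0 for f in true_fractions)
    if not math.isclose(f_oh + f_p + f_cp, 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 100")
    rng = np.random.default_rng(seed)
    detect = (f_oh, f_oh + f_p, f_oh + f_p + f_cp)
    triples = []
    for _ in range(n_replicates):
        cts, cens = [], []
        for d in detect:
            ct = (
                math.inf
                if d <= 0
                else c0 - math.log(d * total_amount, efficiency)
            )
            if math.isfinite(ct) and noise_sd > 0:
                ct += rng.normal(0.0, noise_sd)
            if ct >= CENSOR_CT:  # undetermined well: template below detection
                cts.append(CENSOR_CT)
                cens.append(True)
            else:
                cts.append(ct)
                cens.append(False)
        triples.append(CtTriple(cts[0], cts[1], cts[2], cens[0], cens[1], cens[2]))
    return triples
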