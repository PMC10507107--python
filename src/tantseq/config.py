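"""Pipeline configuration.

Defaults follow the library chemistry: 6-nt sublibrary barcodes GACGTA
(3'-OH, T4 Rnl2 adapter) and CTATCG (3'-cP, RtcB adapter); post-trim reads
kept at 21-46 nt (insert 15-40 nt once the barcode is stripped); mean
Phred >= 30; tiered mapping budget of 2 edits (mismatches + gaps); species
named once mean reads exceed 2; differential calls at adjusted P < 0.01
and |log2 fold change| >= 2.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

#: Constant 3'-adapter that follows the chemistry barcode in every read.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

BARCODE_LENGTH = 6


@dataclass
class PipelineConfig:
    barcode_oh: str = "GACGTA"
    barcode_cp: str = "CTATCG"
    adapter: str = DEFAULT_ADAPTER
    min_len: int = 21
    max_len: int = 46
    phred_threshold: float = 30.0
    quality_rule: str = "mean"  # "mean" or "fraction" (fastp-style qualified-base rule)
    max_low_quality_fraction: float = 0.2
    max_edits: int = 2
    min_adapter_overlap: int = 8
    ligation_eff_oh: float = 1.0
    ligation_eff_cp: float = 1.0
    naming_min_mean_reads: float = 2.0
    de_alpha: float = 0.01
    de_min_abs_log2fc: float = 2.0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("barcode_oh", "barcode_cp"):
            bc = getattr(self, name)
            if len(bc) != BARCODE_LENGTH or set(bc) - set("ACGT"):
                raise ValueError(f"{name} must be a 6-mer over ACGT, got {bc!r}")
        if self.barcode_oh == self.barcode_cp:
            raise ValueError("barcode_oh and barcode_cp must differ")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not (0 < self.ligation_eff_oh <= 1) or not (0 < self.ligation_eff_cp <= 1):
            raise ValueError("ligation efficiencies must lie in (0, 1]")
        if self.quality_rule not in ("mean", "fraction"):
            raise ValueError("quality_rule must be 'mean' or 'fraction'")
        if self.max_edits < 0:
            raise ValueError("max_edits must be >= 0")

    @property
    def min_insert_len(self) -> int:
        return self.min_len - BARCODE_LENGTH

    @property
    def max_insert_len(self) -> int:
        return self.max_len - BARCODE_LENGTH

    def as_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the configuration, stamped into output headers."""
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = dict(data.get("extra") or {})
        extra.update({k: v for k, v in data.items() if k not in known and k != "extra"})
        return cls(**kwargs, extra=extra)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)
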