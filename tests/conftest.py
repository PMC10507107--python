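from __future__ import annotations

import numpy as np
import pytest

from tantseq.config import PipelineConfig
from tantseq.simulate import build_toy_references, make_spikein_panel, sample_species


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def panel():
    return make_spikein_panel(11)


@pytest.fixture(scope="session")
def registry(panel):
    return build_toy_references(12, spikein_panel=panel)


@pytest.fixture(scope="session")
def species(registry):
    return sample_species(registry, 200, seed=13)


def random_query(rng: np.random.Generator, registry, mutate: bool = True) -> str:
    """A query drawn from the registry (possibly mutated) or fully random."""
    tiers = [t for t in registry if len(t) and t.tier_name != "spikein"]
    length = int(rng.integers(15, 31))
    if rng.random() < 0.25:
        return "".join(rng.choice(list("ACGT"), size=length))
    tier = tiers[rng.integers(len(tiers))]
    ref_id = sorted(tier.sequences)[rng.integers(len(tier.sequences))]
    ref = tier.sequences[ref_id]
    start = int(rng.integers(0, len(ref) - length + 1))
    q = list(ref[start : start + length])
    for _ in range(int(rng.integers(0, 3))):
        pos = int(rng.integers(length))
        q[pos] = rng.choice([b for b in "ACGT" if b != q[pos]])
    return "".join(q)
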