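"""Triplex 3'-end qPCR (TE-qPCR) end-fraction estimator.

Three parallel treatments of the same RNA before polyadenylation and RT
make different 3'-end pools detectable: vehicle leaves only 3'-OH species
polyadenylatable; alkaline phosphatase (AP) additionally exposes 3'-P
species; T4 polynucleotide kinase (T4 Pnk, 3'-phosphatase activity)
additionally opens 2',3'-cyclic phosphates, exposing everything.  The
three Ct values Ct(OH) >= Ct(OH+P) >= Ct(OH+P+cP) are inverted in closed
form, assuming perfect doubling per cycle (efficiency 2):

    cP% = (2^dCt - 1) / 2^dCt,      dCt = Ct(OH+P) - Ct(OH+P+cP)
    P%  = (2^dCt' - 1) / 2^dCt' - cP%,  dCt' = Ct(OH) - Ct(OH+P+cP)
    OH% = 100% - P% - cP%

Under Ct noise the P% (or cP%) intermediate can go slightly negative; the
default clamping policy floors negatives at 0 and lets OH% absorb the
remainder so the three fractions always sum to exactly 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Ct value used to censor an undetectable (zero-template) treatment.
CENSOR_CT = 40.0


@dataclass(frozen=True)
class CtTriple:
    """Ct values from the vehicle / AP / T4 Pnk treatments of one target."""

    ct_oh: float
    ct_ohp: float
    ct_ohpcp: float
    censored_oh: bool = False
    censored_ohp: bool = False
    censored_ohpcp: bool = False

    def __post_init__(self) -> None:
        for name in ("ct_oh", "ct_ohp", "ct_ohpcp"):
            v = getattr(self, name)
            if not getattr(self, "censored_" + name[3:]) and not (0 < v <= 45):
                raise ValueError(f"{name}={v} outside (0, 45] and not censored")


@dataclass(frozen=True)
class EndFractions:
    """Percentages of 3'-OH, 3'-P and 3'-cP ends; sums to 100 after clamping."""

    pct_oh: float
    pct_p: float
    pct_cp: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.pct_oh, self.pct_p, self.pct_cp)


def estimate_end_fractions(
    ct: CtTriple, clamp: bool = True, efficiency: float = 2.0
) -> EndFractions:
    """Invert a Ct triple into (OH%, P%, cP%).

    A censored vehicle or AP Ct is treated as "no detectable template" for
    that pool (fraction 0); a censored T4 Pnk Ct means no template at all
    and raises.  `efficiency` generalises the per-cycle amplification
    factor (the printed closed form assumes 2).  With ``clamp=False`` the
    raw, possibly negative, fractions are returned for auditing.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    if ct.censored_ohpcp:
        raise ValueError("no detectable sRNA: Ct for the all-ends treatment is censored")

    # detectable-pool fractions of total template
    if ct.censored_ohp:
        frac_ohp = 0.0
    else:
        frac_ohp = efficiency ** (ct.ct_ohpcp - ct.ct_ohp)
    if ct.censored_oh:
        frac_oh = 0.0
    else:
        frac_oh = efficiency ** (ct.ct_ohpcp - ct.ct_oh)

    cp = 100.0 * (1.0 - frac_ohp)
    p = 100.0 * (1.0 - frac_oh) - cp
    oh = 100.0 - p - cp
    if not clamp:
        return EndFractions(oh, p, cp)
    cp = min(max(cp, 0.0), 100.0)
    p = min(max(p, 0.0), 100.0 - cp)
    oh = 100.0 - p - cp
    return EndFractions(oh, p, cp)


def estimate_from_replicates(
    triples: list[CtTriple],
    clamp: bool = True,
    efficiency: float = 2.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[EndFractions, tuple[float, float, float]]:
    """Average Ct values per treatment, then invert; with a bootstrap SD.

    Cts are averaged before transformation (the difference from averaging
    fractions is second-order in the replicate noise).  A treatment counts
    as censored only when every replicate is censored; censored wells are
    excluded from the mean otherwise.  Returns (EndFractions,
    (sd_oh, sd_p, sd_cp)) with the SDs from `n_boot` bootstrap resamples
    of the replicate triples (0 when a single replicate is supplied).
    """
    if not triples:
        raise ValueError("need at least one replicate")

    def _mean_triple(ts: list[CtTriple]) -> CtTriple:
        def agg(vals: list[float], cens: list[bool]) -> tuple[float, bool]:
            live = [v for v, c in zip(vals, cens) if not c]
            if not live:
                return CENSOR_CT, True
            return float(np.mean(live)), False

        oh, c_oh = agg([t.ct_oh for t in ts], [t.censored_oh for t in ts])
        ohp, c_ohp = agg([t.ct_ohp for t in ts], [t.censored_ohp for t in ts])
        ohpcp, c_all = agg([t.ct_ohpcp for t in ts], [t.censored_ohpcp for t in ts])
        return CtTriple(oh, ohp, ohpcp, c_oh, c_ohp, c_all)

    point = estimate_end_fractions(_mean_triple(triples), clamp=clamp, efficiency=efficiency)
    if len(triples) < 2 or n_boot <= 0:
        return point, (0.0, 0.0, 0.0)

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(triples), size=len(triples))
        try:
            est = estimate_end_fractions(
                _mean_triple([triples[i] for i in idx]), clamp=clamp, efficiency=efficiency
            )
        except ValueError:
            continue
        boots.append(est.as_tuple())
    if not boots:
        return point, (math.nan, math.nan, math.nan)
    sd = np.std(np.asarray(boots), axis=0, ddof=1)
    return point, (float(sd[0]), float(sd[1]), float(sd[2]))
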