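"""Guide-target duplex alignment and Argonaute (Ago2) slicer-site
prediction.

A small-RNA guide loaded into Ago2 cleaves a complementary target between
the target nucleotides paired with guide positions 10 and 11 (counting
from the guide 5' end) — the canonical slicer geometry, independent of the
guide's 3'-end chemistry.  The duplex is found by an exhaustive
antiparallel complementarity scan (adequate for <= 40-nt fragments; no
thermodynamic scoring).
"""

from __future__ import annotations

from dataclasses import dataclass

from tantseq.io import normalize_sequence

_PAIR = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U in RNA terms

SEED_POSITIONS = range(2, 9)  # guide positions 2-8


@dataclass(frozen=True)
class GuideTargetDuplex:
    """Antiparallel guide/target pairing at a fixed register.

    `anchor` is the 1-based target position paired with guide position 1
    (the guide 5' end pairs the 3'-most target base of the duplex); guide
    position i pairs target position anchor - i + 1.  `paired_mask[i-1]`
    flags Watson-Crick (or, if enabled, wobble) pairing at guide position i.
    """

    guide: str
    target: str
    anchor: int
    paired_mask: tuple[bool, ...]
    weak: bool = False  # fewer than 7 paired seed positions

    def target_position(self, guide_pos: int) -> int:
        """1-based target position paired with `guide_pos`."""
        if not 1 <= guide_pos <= len(self.guide):
            raise ValueError("guide position out of range")
        return self.anchor - guide_pos + 1

    @property
    def n_paired(self) -> int:
        return sum(self.paired_mask)


def _pairs(g: str, t: str, allow_gu: bool) -> bool:
    return (g, t) in _PAIR or (allow_gu and (g, t) in _WOBBLE)


def align_duplex(guide: str, target: str, allow_gu: bool = False) -> GuideTargetDuplex:
    """Best antiparallel register of a guide on a longer target.

    Maximises the number of paired guide positions (G:U counted only with
    `allow_gu`); ties prefer the register with the longest contiguous run
    of paired seed positions (guide 2-8), then the smallest target offset
    of the duplex.  A duplex pairing fewer than 7 of the 7 seed positions
    is flagged weak.
    """
    guide = normalize_sequence(guide)
    target = normalize_sequence(target)
    m, n = len(guide), len(target)
    if n < m:
        raise ValueError("target must be at least as long as the guide")

    best: tuple[int, int, int] | None = None  # (-paired, -seed_run, anchor)
    best_mask: tuple[bool, ...] | None = None
    for anchor in range(m, n + 1):  # guide pos m pairs target anchor-m+1 >= 1
        mask = tuple(
            _pairs(guide[i - 1], target[anchor - i], allow_gu) for i in range(1, m + 1)
        )
        run = best_run = 0
        for i in SEED_POSITIONS:
            if i <= m and mask[i - 1]:
                run += 1
                best_run = max(best_run, run)
            else:
                run = 0
        key = (-sum(mask), -best_run, anchor)
        if best is None or key < best:
            best = key
            best_mask = mask
    assert best is not None and best_mask is not None
    anchor = best[2]
    n_seed_paired = sum(best_mask[i - 1] for i in SEED_POSITIONS if i <= m)
    return GuideTargetDuplex(
        guide=guide,
        target=target,
        anchor=anchor,
        paired_mask=best_mask,
        weak=n_seed_paired < 7,
    )


def predict_cleavage_site(duplex: GuideTargetDuplex) -> tuple[int, int, int]:
    """Locate the scissile bond: (guide_flank_5, guide_flank_3, target_cut).

    The cut lies between the target nucleotides paired with guide positions
    10 and 11; the guide-side flanks are therefore always exactly (10, 11).
    `target_cut` is the 1-based target position of the last base of the 5'
    product (the 3' product begins at the base paired with guide position
    10).  Guides shorter than 11 nt, or duplexes unpaired at positions
    10/11, are rejected.
    """
    if len(duplex.guide) < 11:
        raise ValueError("guide too short for slicer geometry (needs >= 11 nt)")
    if not (duplex.paired_mask[9] and duplex.paired_mask[10]):
        raise ValueError("non-cleavable duplex: guide positions 10/11 unpaired")
    target_cut = duplex.target_position(11)  # == target_position(10) - 1
    if target_cut < 1 or target_cut >= len(duplex.target):
        raise ValueError("cleavage site falls outside the target")
    return 10, 11, target_cut


def product_sequences(duplex: GuideTargetDuplex, target_cut: int) -> tuple[str, str]:
    """(5' product, 3' product) of target cleavage at `target_cut`.

    The 5' product is target[1..target_cut]; concatenating the two products
    reconstitutes the target exactly.
    """
    if not 1 <= target_cut < len(duplex.target):
        raise ValueError("cut position must be an internal bond")
    return duplex.target[:target_cut], duplex.target[target_cut:]


def fraction_cleaved(density_5prime_product: float, density_uncleaved: float) -> float:
    """Cleaved fraction from gel densitometry: d5 / (d5 + d_uncleaved)."""
    if density_5prime_product < 0 or density_uncleaved < 0:
        raise ValueError("densities must be >= 0")
    total = density_5prime_product + density_uncleaved
    if total == 0:
        raise ValueError("both densities are zero")
    return density_5prime_product / total
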