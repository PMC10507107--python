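"""Abundance adjustment, distributions, terminal-nucleotide enrichment,
replicate correlation and top-N overlap.

The two chemistry sublibraries are captured by different ligases (T4 Rnl2
for 3'-OH, RtcB for 3'-cP) with different efficiencies, so raw read totals
are not comparable across chemistries; `adjust_abundance` divides each raw
total by its ligation efficiency before forming relative percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

RNA_BASES = ("A", "C", "G", "U")
_DNA_TO_RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}


def adjust_abundance(
    raw_reads_oh: float | pd.Series,
    raw_reads_cp: float | pd.Series,
    eff_oh: float,
    eff_cp: float,
) -> tuple:
    """Ligation-efficiency-adjusted relative percentages (OH%, cP%).

    adjusted_x = raw_x / eff_x; percent_x = 100 * adjusted_x / sum.
    Accepts scalars or aligned per-biotype Series.
    """
    if not (0 < eff_oh <= 1) or not (0 < eff_cp <= 1):
        raise ValueError("efficiencies must lie in (0, 1]")
    adj_oh = raw_reads_oh / eff_oh
    adj_cp = raw_reads_cp / eff_cp
    total = adj_oh + adj_cp
    if np.ndim(total) == 0:
        if total == 0:
            raise ValueError("both raw totals are zero")
        return 100.0 * adj_oh / total, 100.0 * adj_cp / total
    if (np.asarray(total) == 0).all():
        raise ValueError("both raw totals are zero")
    return 100.0 * adj_oh / total, 100.0 * adj_cp / total


def length_distribution(
    species: pd.DataFrame,
    length_range: tuple[int, int] = (15, 30),
    count_col: str = "mean_reads",
) -> pd.DataFrame:
    """Read-weighted length histogram per (biotype, chemistry) stratum.

    Rows are lengths over `length_range`; columns are "{biotype}|{chem}".
    Histogram masses sum to the stratum totals (species outside the length
    window are excluded, as in a 15-30 nt display window).
    """
    lo, hi = length_range
    lengths = range(lo, hi + 1)
    sub = species[(species["length"] >= lo) & (species["length"] <= hi)]
    table = pd.DataFrame(0.0, index=list(lengths), columns=[])
    for (biotype, chem), grp in sub.groupby(["biotype", "chemistry"], sort=True):
        col = f"{biotype}|{chem}"
        hist = grp.groupby("length")[count_col].sum()
        table[col] = [float(hist.get(L, 0.0)) for L in lengths]
    table.index.name = "length"
    return table


def precursor_distribution(
    species: pd.DataFrame,
    biotype: str = "tsRNA",
    count_col: str = "mean_reads",
) -> dict[str, pd.DataFrame]:
    """Per-precursor (5' start offset x read length) count matrices.

    Offsets are 1-based from the precursor 5' end, so 5'-fragments occupy
    only offset-1 rows; column sums over offsets reproduce the length
    distribution of the same stratum.
    """
    out: dict[str, pd.DataFrame] = {}
    sub = species[species["biotype"] == biotype]
    for ref_id, grp in sub.groupby("reference_id", sort=True):
        mat = (
            grp.groupby(["start", "length"])[count_col]
            .sum()
            .unstack(fill_value=0.0)
            .sort_index()
        )
        mat.index.name = "start_offset"
        mat.columns.name = "length"
        out[ref_id] = mat
    return out


@dataclass
class EnrichmentMatrix:
    """Terminal five-nucleotide composition and log2 enrichment.

    ``frequencies``: 4 x n_positions over (A, C, G, U), each position
    column summing to 1.  For ``end='3prime'`` position 1 is the 3'
    terminal base and positions run inward; for ``end='5prime'`` position 1
    is the 5' terminal base.  ``log2_enrichment`` = log2(freq / background)
    elementwise where background > 0 (NaN elsewhere).
    """

    end: str
    positions: tuple[int, ...]
    frequencies: pd.DataFrame
    background: pd.Series
    log2_enrichment: pd.DataFrame


def _composition(weights_by_seq: Mapping[str, float]) -> pd.Series:
    counts = dict.fromkeys(RNA_BASES, 0.0)
    for seq, w in weights_by_seq.items():
        for base in seq:
            rb = _DNA_TO_RNA.get(base)
            if rb is not None:
                counts[rb] += w
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no countable bases")
    return pd.Series({b: counts[b] / total for b in RNA_BASES})


def terminal_nucleotide_matrix(
    species: pd.DataFrame,
    end: str = "3prime",
    weighting: str = "reads",
    n_positions: int = 5,
    background: pd.Series | None = None,
    count_col: str = "mean_reads",
) -> EnrichmentMatrix:
    """Composition of the terminal `n_positions` nucleotides of a sublibrary.

    ``weighting='reads'`` weights each species by its read count;
    ``'unique'`` weights every species equally.  The default background is
    the overall base composition of the full sequences (same weighting).
    """
    if end not in ("5prime", "3prime"):
        raise ValueError("end must be '5prime' or '3prime'")
    if weighting not in ("reads", "unique"):
        raise ValueError("weighting must be 'reads' or 'unique'")
    seqs = species["sequence"].tolist()
    if any(len(s) < n_positions for s in seqs):
        raise ValueError(f"all sequences must be >= {n_positions} nt")
    if not seqs:
        raise ValueError("empty species table")
    w = (
        species[count_col].astype(float).tolist()
        if weighting == "reads"
        else [1.0] * len(seqs)
    )
    freq = pd.DataFrame(0.0, index=list(RNA_BASES), columns=range(1, n_positions + 1))
    for seq, weight in zip(seqs, w):
        for pos in range(1, n_positions + 1):
            base = seq[-pos] if end == "3prime" else seq[pos - 1]
            rb = _DNA_TO_RNA.get(base)
            if rb is not None:
                freq.loc[rb, pos] += weight
    colsum = freq.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("zero total weight")
    freq = freq / colsum
    if background is None:
        background = _composition(dict(zip(seqs, w)))
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = pd.DataFrame(
            np.where(
                background.values[:, None] > 0,
                np.log2(freq.values / background.values[:, None]),
                np.nan,
            ),
            index=freq.index,
            columns=freq.columns,
        )
    return EnrichmentMatrix(
        end=end,
        positions=tuple(range(1, n_positions + 1)),
        frequencies=freq,
        background=background,
        log2_enrichment=enr,
    )


def replicate_correlation(counts_a: pd.Series, counts_b: pd.Series) -> float:
    """Pearson r between two replicates on log2(count + 1).

    Computed over the union of species; a species absent from one replicate
    counts 0 there.
    """
    union = counts_a.index.union(counts_b.index)
    if len(union) < 2:
        return float("nan")
    a = np.log2(counts_a.reindex(union, fill_value=0).astype(float) + 1.0)
    b = np.log2(counts_b.reindex(union, fill_value=0).astype(float) + 1.0)
    if a.std() == 0 or b.std() == 0:
        return 1.0 if a.equals(b) else float("nan")
    return float(stats.pearsonr(a, b)[0])


def _top_n_keys(species: pd.DataFrame, n: int) -> list[tuple[str, str]]:
    order = species.sort_values(
        ["mean_reads", "sequence"], ascending=[False, True], kind="mergesort"
    )
    return [(r.sequence, r.chemistry) for r in order.head(n).itertuples()]


def top_overlap(
    species_a: pd.DataFrame, species_b: pd.DataFrame, n: int, denominator: str = "n"
) -> dict:
    """Overlap of the top-n most abundant species of two tables.

    Species are keyed by (sequence, chemistry), ranked by mean_reads with
    deterministic ties (lexicographic sequence).  ``overlap_pct`` uses n as
    the denominator by default; ``denominator='union'`` gives the Jaccard
    variant.  Venn counts |A only|, |B only| and |A and B| are reported.
    """
    m = min(len(species_a), len(species_b))
    if n > m:
        warnings.warn(f"n={n} exceeds the smaller table ({m}); truncating", stacklevel=2)
        n = m
    a = set(_top_n_keys(species_a, n))
    b = set(_top_n_keys(species_b, n))
    inter = a & b
    denom = n if denominator == "n" else len(a | b)
    return {
        "n": n,
        "intersection": len(inter),
        "a_only": len(a - b),
        "b_only": len(b - a),
        "overlap_pct": 100.0 * len(inter) / denom if denom else 0.0,
    }
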