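"""Two-group differential expression of small-RNA species counts.

Counts are CPM-normalised per library; each species gets a conditional
exact binomial test (the pooled group-2 count against the library-size
ratio null, conditioned on the pooled total — a negative binomial with
zero dispersion under conditioning), p-values are adjusted by
Benjamini-Yekutieli (valid under arbitrary dependence), and species are
called differential at adjusted P < 0.01 and |log2 fold change| >= 2,
restricted to species with average raw reads >= 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tantseq.config import PipelineConfig


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per column; a zero-total library raises."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero-count libraries: {bad}")
    return counts * 1e6 / totals


def exact_count_test(
    counts1: np.ndarray | list,
    counts2: np.ndarray | list,
    libsize1: np.ndarray | list,
    libsize2: np.ndarray | list,
) -> tuple[float, float]:
    """(log2fc, p) for one species across two replicate groups.

    log2fc = log2((mean CPM2 + 0.5) / (mean CPM1 + 0.5)); p is the
    two-sided exact binomial probability of the pooled group-2 count given
    the pooled total, under the library-size-ratio null.  Both pooled
    counts zero -> (0, 1).
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    l1 = np.asarray(libsize1, dtype=float)
    l2 = np.asarray(libsize2, dtype=float)
    if c1.size == 0 or c2.size == 0:
        raise ValueError("each group needs at least one replicate")
    cpm1 = (c1 * 1e6 / l1).mean()
    cpm2 = (c2 * 1e6 / l2).mean()
    log2fc = float(np.log2((cpm2 + 0.5) / (cpm1 + 0.5)))
    pooled = int(c1.sum() + c2.sum())
    if pooled == 0:
        return 0.0, 1.0
    p_null = l2.sum() / (l1.sum() + l2.sum())
    p = stats.binomtest(int(c2.sum()), pooled, p_null, alternative="two-sided").pvalue
    return log2fc, float(min(p, 1.0))


def benjamini_yekutieli(p_values: np.ndarray | list) -> np.ndarray:
    """BY-adjusted p-values: BH with the harmonic correction c(m) = sum 1/k."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_by")[1]


def call_de(
    counts: pd.DataFrame,
    groups: dict[str, list[str]] | tuple[list[str], list[str]],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Volcano-ready DE table for a two-group design.

    `counts`: species x samples raw count matrix.  `groups`: the two
    sample-name lists (dict of two entries or a pair).  Species with mean
    raw reads < 2 across all samples are excluded before testing.  is_de
    <=> adj_p < de_alpha and |log2fc| >= de_min_abs_log2fc.
    """
    if config is None:
        config = PipelineConfig()
    if isinstance(groups, dict):
        if len(groups) != 2:
            raise ValueError("exactly two groups required")
        (name1, g1), (name2, g2) = groups.items()
    else:
        g1, g2 = groups
        name1, name2 = "group1", "group2"
    all_samples = list(g1) + list(g2)
    missing = [s for s in all_samples if s not in counts.columns]
    if missing:
        raise ValueError(f"samples not in count matrix: {missing}")

    lib1 = counts[list(g1)].sum(axis=0).to_numpy()
    lib2 = counts[list(g2)].sum(axis=0).to_numpy()
    mean_reads = counts[all_samples].mean(axis=1)
    kept = counts.loc[mean_reads >= 2.0]

    rows = []
    for species_id, row in kept.iterrows():
        lfc, p = exact_count_test(
            row[list(g1)].to_numpy(), row[list(g2)].to_numpy(), lib1, lib2
        )
        rows.append((species_id, lfc, p, float(mean_reads.loc[species_id])))
    result = pd.DataFrame(rows, columns=["species_id", "log2fc", "p_value", "mean_reads"])
    if not result.empty:
        result["adj_p"] = benjamini_yekutieli(result["p_value"].to_numpy())
        result["is_de"] = (result["adj_p"] < config.de_alpha) & (
            result["log2fc"].abs() >= config.de_min_abs_log2fc
        )
    else:
        result["adj_p"] = pd.Series(dtype=float)
        result["is_de"] = pd.Series(dtype=bool)
    result.attrs["groups"] = {name1: list(g1), name2: list(g2)}
    return result.set_index("species_id")
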