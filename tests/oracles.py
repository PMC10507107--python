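"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own search code paths: window
placement is an exhaustive scan over every (start, length, strand) window
scored with edlib's global aligner; the multiple-testing adjustment is a
direct transcription of the step-up formula.
"""

from __future__ import annotations

import edlib
import numpy as np

from tantseq.classify import reverse_complement


def oracle_best_in_sequence(query: str, ref: str, k: int):
    """Exhaustive window scan; returns (edits, start0, end0) or None."""
    m, n = len(query), len(ref)
    best = None
    for s in range(0, n - (m - k) + 1):
        for L in range(max(1, m - k), min(n - s, m + k) + 1):
            d = edlib.align(query, ref[s : s + L], mode="NW", k=k)["editDistance"]
            if d == -1:
                continue
            cand = (d, s, s + L - 1)
            if best is None or cand < best:
                best = cand
    return best


def oracle_align_tier(query: str, tier, k: int):
    best_key = None
    best = None
    for ref_id in sorted(tier.sequences):
        ref = tier.sequences[ref_id]
        strands = ("+", "-") if tier.search_both_strands else ("+",)
        for strand in strands:
            target = ref if strand == "+" else reverse_complement(ref)
            hit = oracle_best_in_sequence(query, target, k)
            if hit is None:
                continue
            cost, s0, e0 = hit
            if strand == "-":
                n = len(ref)
                s0, e0 = n - 1 - e0, n - 1 - s0
            key = (cost, ref_id, s0, 0 if strand == "+" else 1, e0)
            if best_key is None or key < best_key:
                best_key = key
                best = (ref_id, s0 + 1, e0 + 1, strand, cost)
    return best


def oracle_classify(query: str, registry, k: int):
    """Two-round priority walk using the exhaustive window oracle."""
    for tier in registry:
        hit = oracle_align_tier(query, tier, 0)
        if hit is not None:
            return tier.tier_name, hit, 1
    for tier in registry:
        hit = oracle_align_tier(query, tier, k)
        if hit is not None:
            return tier.tier_name, hit, 2
    return None


def oracle_by_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up, transcribed from the formula:
    adj_(i) = min(1, min_{j>=i} p_(j) * m * c(m) / j), c(m) = sum 1/k."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m * c_m / rank)
        adj_sorted[rank - 1] = min(1.0, running)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def oracle_best_register(guide: str, target: str, allow_gu: bool = False):
    """Brute-force duplex register maximisation (mirror of the documented
    objective, computed independently)."""
    pair = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
    if allow_gu:
        pair = pair | {("G", "T"), ("T", "G")}
    m, n = len(guide), len(target)
    best = None
    for anchor in range(m, n + 1):
        mask = [(guide[i - 1], target[anchor - i]) in pair for i in range(1, m + 1)]
        run = best_run = 0
        for i in range(2, min(8, m) + 1):
            if mask[i - 1]:
                run += 1
                best_run = max(best_run, run)
            else:
                run = 0
        key = (-sum(mask), -best_run, anchor)
        if best is None or key < best:
            best = key
    return best[2]
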