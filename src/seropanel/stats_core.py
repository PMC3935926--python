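"""Per-feature test statistics.

The screening statistic is the minimum-over-cutoffs hypergeometric upper
tail ("M score"): for each candidate intensity cutoff, the probability of
seeing at least the observed number of cases above the cutoff by chance,
minimized over all cutoffs. One-sided, case-elevated.

Also: Welch two-sample t test, Benjamini-Hochberg FDR adjustment, and
deterministic p-value ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp


# ---------------------------------------------------------------------------
# hypergeometric upper tail
# ---------------------------------------------------------------------------

def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_upper_tail(a: int, k: int, n1: int, n2: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(population n1+n2, n1 successes,
    k draws), computed by log-space summation of exact terms.

    ``a`` is the observed number of cases among the ``k`` samples above a
    cutoff, with ``n1`` cases and ``n2`` controls overall.
    """
    if not (0 <= a <= min(k, n1)):
        raise ValueError(f"need 0 <= a <= min(k, n1); got a={a}, k={k}, n1={n1}")
    if k - a > n2:
        raise ValueError(f"k - a = {k - a} exceeds number of controls n2={n2}")
    if k > n1 + n2:
        raise ValueError(f"k={k} exceeds population {n1 + n2}")
    if a == 0:
        return 1.0
    denom = _log_comb(n1 + n2, k)
    terms = [
        _log_comb(n1, x) + _log_comb(n2, k - x) - denom
        for x in range(a, min(k, n1) + 1)
    ]
    return float(min(1.0, math.exp(logsumexp(terms))))


@lru_cache(maxsize=64)
def _tail_table(n1: int, n2: int) -> np.ndarray:
    """Table T[a, k] = P(X >= a | k draws); shape (n1+1, n1+n2+1).
    Invalid (a, k) combinations hold NaN."""
    n = n1 + n2
    table = np.full((n1 + 1, n + 1), np.nan)
    for k in range(n + 1):
        amax = min(k, n1)
        amin_valid = max(0, k - n2)
        logs = np.array(
            [
                _log_comb(n1, x) + _log_comb(n2, k - x) - _log_comb(n, k)
                for x in range(amin_valid, amax + 1)
            ]
        )
        pmf = np.exp(logs)
        tail = np.minimum(1.0, np.cumsum(pmf[::-1])[::-1])
        for a in range(amax + 1):
            if a <= amin_valid:
                table[a, k] = 1.0
            else:
                table[a, k] = tail[a - amin_valid]
    return table


# ---------------------------------------------------------------------------
# M score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MScoreResult:
    p_value: float
    best_cutoff: float
    cases_above: int
    controls_above: int


def m_score(case_values: Sequence[float], control_values: Sequence[float]) -> MScoreResult:
    """Minimum hypergeometric-tail p over intensity cutoffs (case-high).

    Candidate cutoffs are the midpoints between consecutive distinct pooled
    values plus one cutoff above the pooled maximum; counts use strict '>'.
    Ties in p are broken in favor of the largest cutoff.
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = cases.size, controls.size
    pooled = np.concatenate([cases, controls])
    is_case = np.concatenate([np.ones(n1, bool), np.zeros(n2, bool)])

    order = np.argsort(-pooled, kind="stable")
    sorted_vals = pooled[order]
    case_cum = np.cumsum(is_case[order])
    table = _tail_table(n1, n2)

    n = n1 + n2
    best_p, best_k = 1.0, 0  # k = 0 is the above-maximum cutoff (largest)
    for k in range(1, n):  # boundaries between distinct consecutive values
        if sorted_vals[k - 1] <= sorted_vals[k]:
            continue
        a = int(case_cum[k - 1])
        p = float(table[a, k])
        if p < best_p:
            best_p, best_k = p, k

    if best_k == 0:
        cutoff = float(sorted_vals[0] + 1.0)
        a = b = 0
    else:
        cutoff = float((sorted_vals[best_k - 1] + sorted_vals[best_k]) / 2.0)
        a = int(case_cum[best_k - 1])
        b = best_k - a
    return MScoreResult(p_value=best_p, best_cutoff=cutoff, cases_above=a, controls_above=b)


def m_score_matrix(values: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Vectorized M-score p-values for many features at once.

    ``values`` is features x samples; ``case_mask`` is a boolean sample
    vector. Returns one p per feature, identical to :func:`m_score` row-wise.
    """
    values = np.asarray(values, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    n1 = int(case_mask.sum())
    n2 = int((~case_mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    table = _tail_table(n1, n2)

    order = np.argsort(-values, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=1)
    case_cum = np.cumsum(case_mask[order], axis=1)

    # valid boundary after position k-1 (1-based k) requires a strict drop
    boundary = sorted_vals[:, :-1] > sorted_vals[:, 1:]  # shape (m, n-1)
    a = case_cum[:, :-1]  # cases among top-k for k = 1..n-1
    k = np.arange(1, n)[None, :]
    p = table[a, np.broadcast_to(k, a.shape)]
    p = np.where(boundary, p, 1.0)
    return np.minimum(1.0, p.min(axis=1, initial=1.0))


# ---------------------------------------------------------------------------
# Welch t, BH FDR, ranking
# ---------------------------------------------------------------------------

def welch_t(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Two-sided unequal-variance two-sample t-test p-value."""
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size < 2 or controls.size < 2:
        raise ValueError("Welch t requires at least 2 observations per group")
    if cases.var(ddof=1) == 0 and controls.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups: t undefined")
    return float(sps.ttest_ind(cases, controls, equal_var=False).pvalue)


def welch_t_matrix(values: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Row-wise Welch t p-values for a features x samples matrix."""
    values = np.asarray(values, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    res = sps.ttest_ind(values[:, case_mask], values[:, ~case_mask], axis=1, equal_var=False)
    return np.nan_to_num(np.asarray(res.pvalue), nan=1.0)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def rank_features(p_values: Sequence[float], feature_ids: Sequence[str]) -> np.ndarray:
    """1-based positions by ascending p, ties broken by lexicographic id.
    Returned array is aligned with the input order."""
    p = np.asarray(p_values, dtype=float)
    ids = list(feature_ids)
    if p.size != len(ids):
        raise ValueError("p_values and feature_ids lengths differ")
    order = sorted(range(p.size), key=lambda i: (p[i], ids[i]))
    positions = np.empty(p.size, dtype=int)
    for pos, i in enumerate(order, start=1):
        positions[i] = pos
    return positions
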