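"""Non-parametric repeated-measures statistics: Friedman test and Dunn post-hoc.

Designed for small complete-block designs (n subjects x k conditions, here n = 7,
k = 3 intensity conditions).  The Friedman statistic uses within-subject mid-ranks
with the standard tie correction; p-values come from the chi-square approximation or,
for small designs, from exact enumeration of all (k!)^n within-subject rank
assignments.  Dunn's pairwise z statistics compare mean within-block ranks; both the
Bonferroni-adjusted (classic Dunn) and unadjusted ("LSD") modes are reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "FriedmanResult",
    "change_scores",
    "friedman",
    "dunn_posthoc",
]

#: largest number of enumerated rank assignments for the exact Friedman p-value
_EXACT_LIMIT = 2_000_000


def change_scores(
    first: pd.DataFrame,
    last: pd.DataFrame,
    keys: tuple[str, ...] = ("subject", "condition"),
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-subject, per-condition change scores: ``last - first`` for each variable.

    Both tables must contain exactly the same key combinations.  Swapping the
    arguments negates every score.
    """
    keys = list(keys)
    if variables is None:
        variables = [c for c in first.columns if c not in keys]
    missing = [c for c in keys + variables if c not in first.columns or c not in last.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    a = first.set_index(keys)[variables].sort_index()
    b = last.set_index(keys)[variables].sort_index()
    if not a.index.equals(b.index):
        raise ValueError("first/last tables have mismatched subject/condition keys")
    return (b - a).reset_index()


def _rank_matrix(data: np.ndarray) -> np.ndarray:
    """Within-subject mid-ranks (ties averaged)."""
    return np.apply_along_axis(sstats.rankdata, 1, data)


def _tie_correction(data: np.ndarray) -> float:
    """Standard Friedman tie-correction factor C in (0, 1]."""
    n, k = data.shape
    t_sum = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        t_sum += float(np.sum(counts**3 - counts))
    return 1.0 - t_sum / (n * k * (k**2 - 1))


def _q_statistic(rank_colsums: np.ndarray, n: int, k: int, correction: float) -> np.ndarray:
    q = 12.0 / (n * k * (k + 1)) * np.sum(np.asarray(rank_colsums) ** 2, axis=-1) - 3.0 * n * (k + 1)
    return q / correction


@dataclass
class FriedmanResult:
    statistic: float
    df: int
    pvalue: float
    method: str
    n_subjects: int
    n_conditions: int


def _as_matrix(data) -> np.ndarray:
    m = np.asarray(data.values if isinstance(data, pd.DataFrame) else data, dtype=float)
    if m.ndim != 2:
        raise ValueError("repeated measures must be a 2-D subjects x conditions array")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(m)):
        raise ValueError("incomplete blocks: all cells must be present and finite")
    return m


def friedman(data, method: str = "auto") -> FriedmanResult:
    """Friedman rank test for a complete block design.

    Parameters
    ----------
    data
        ``n x k`` matrix (or DataFrame) of one dependent variable, rows = subjects,
        columns = conditions.
    method
        ``"chisq"`` for the chi-square approximation (df = k - 1), ``"exact"`` for
        full enumeration of within-subject rank permutations (feasible for small n
        and k, e.g. (3!)^7 = 279,936 at n = 7, k = 3), or ``"auto"`` to pick exact
        whenever the enumeration is small enough.

    Notes
    -----
    The statistic is ``Q = [12 / (n k (k+1))] * sum_j R_j^2 - 3 n (k+1)`` on
    within-subject mid-ranks, divided by the tie-correction factor
    ``1 - sum(t^3 - t) / (n k (k^2 - 1))``.  If every block is completely tied the
    statistic is 0 and the p-value 1.
    """
    m = _as_matrix(data)
    n, k = m.shape
    ranks = _rank_matrix(m)
    correction = _tie_correction(m)
    if correction <= 0:  # every block completely tied
        return FriedmanResult(0.0, k - 1, 1.0, "degenerate", n, k)
    q_obs = float(_q_statistic(ranks.sum(axis=0), n, k, correction))

    n_perm = math.factorial(k) ** n
    if method == "auto":
        method = "exact" if n_perm <= _EXACT_LIMIT else "chisq"
    if method == "chisq":
        p = float(sstats.chi2.sf(q_obs, k - 1))
    elif method == "exact":
        if n_perm > _EXACT_LIMIT:
            raise ValueError("design too large for exact enumeration")
        colsums = np.zeros((1, k))
        for row in ranks:
            perms = np.array(sorted({p for p in itertools.permutations(row)}))
            colsums = (colsums[:, None, :] + perms[None, :, :]).reshape(-1, k)
        q_all = _q_statistic(colsums, n, k, correction)
        p = float(np.mean(q_all >= q_obs - 1e-9))
    else:
        raise ValueError("method must be 'auto', 'chisq', or 'exact'")
    return FriedmanResult(q_obs, k - 1, p, method, n, k)


def dunn_posthoc(
    data,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Dunn's pairwise post-hoc comparisons after a Friedman test.

    For each condition pair the statistic is
    ``z = |Rbar_a - Rbar_b| / sqrt(k (k+1) / (6 n))`` on mean within-block ranks.
    ``adjust="bonferroni"`` multiplies the two-sided normal p by the number of pairs
    (classic Dunn); ``adjust="none"`` reports unadjusted p ("LSD" reading).  The mode
    used is recorded in the output.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    m = _as_matrix(data)
    n, k = m.shape
    if labels is None:
        labels = (
            list(map(str, data.columns)) if isinstance(data, pd.DataFrame)
            else [f"C{j}" for j in range(k)]
        )
    mean_ranks = _rank_matrix(m).mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    n_pairs = k * (k - 1) // 2
    rows = []
    for a, b in itertools.combinations(range(k), 2):
        z = abs(mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * float(sstats.norm.sf(z))
        p_adj = min(1.0, p * n_pairs)
        p_used = p_adj if adjust == "bonferroni" else p
        rows.append(
            {
                "condition_a": labels[a],
                "condition_b": labels[b],
                "mean_rank_a": mean_ranks[a],
                "mean_rank_b": mean_ranks[b],
                "z": z,
                "p_unadjusted": p,
                "p_bonferroni": p_adj,
                "p": p_used,
                "significant": p_used < alpha,
                "adjustment": adjust,
            }
        )
    return pd.DataFrame(rows)
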