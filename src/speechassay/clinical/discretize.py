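"""Jenks natural-breaks discretization and the Bonferroni threshold."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretizationResult:
    labels: np.ndarray  # group index per input value; -1 where non-finite
    k: int
    gof: float
    breaks: list  # upper edge value of each group except the last


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests, at 4 decimals."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return round(alpha / n_tests, 4)


def _jenks_partition(sorted_vals: np.ndarray, k: int):
    """Exact dynamic-programming minimization of within-group sum of squares.

    Returns (group sizes, within-group SS) for the optimal ordered partition
    of ``sorted_vals`` into ``k`` contiguous groups.
    """
    n = sorted_vals.size
    csum = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    csq = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])

    def ssq(i, j):  # inclusive i..j, 0-based
        s = csum[j + 1] - csum[i]
        q = csq[j + 1] - csq[i]
        return q - s * s / (j + 1 - i)

    # dp[m][j]: min SS partitioning vals[0..j] into m+1 groups
    dp = np.full((k, n), np.inf)
    back = np.zeros((k, n), dtype=int)
    for j in range(n):
        dp[0, j] = ssq(0, j)
    for m in range(1, k):
        for j in range(m, n):
            best, arg = np.inf, m
            for i in range(m, j + 1):
                cand = dp[m - 1, i - 1] + ssq(i, j)
                if cand < best:
                    best, arg = cand, i
            dp[m, j] = best
            back[m, j] = arg
    cuts = []
    j = n - 1
    for m in range(k - 1, 0, -1):
        i = back[m, j]
        cuts.append(i)
        j = i - 1
    cuts = sorted(cuts)
    sizes = np.diff([0, *cuts, n])
    return sizes, float(dp[k - 1, n - 1])


def jenks_discretize(
    values,
    k_range: tuple = (2, 4),
    gof_min: float = 0.90,
) -> DiscretizationResult:
    """Natural-breaks grouping with goodness-of-fit-driven group count.

    The number of groups is the smallest k in ``k_range`` whose goodness of
    fit, 1 - (within-group SS) / (total SS about the grand mean), exceeds
    ``gof_min``; if none does, the largest k is used. All-identical input is
    rejected (goodness of fit undefined). Non-finite values get label -1.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    vals = values[finite]
    k_min, k_max = k_range
    if np.unique(vals).size < k_min:
        raise ValueError(
            f"need at least {k_min} distinct finite values, got {np.unique(vals).size}"
        )
    total_ss = float(np.sum((vals - vals.mean()) ** 2))
    if total_ss == 0.0:
        raise ValueError("all values identical: goodness of fit undefined")
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]

    chosen = None
    for k in range(k_min, k_max + 1):
        if np.unique(vals).size < k:
            break
        sizes, wss = _jenks_partition(sorted_vals, k)
        gof = 1.0 - wss / total_ss
        chosen = (k, gof, sizes)
        if gof > gof_min:
            break
    k, gof, sizes = chosen
    bounds = np.cumsum(sizes)[:-1]
    sorted_labels = np.zeros(sorted_vals.size, dtype=int)
    for b in bounds:
        sorted_labels[b:] += 1
    lab_fin = np.empty(vals.size, dtype=int)
    lab_fin[order] = sorted_labels
    labels = np.full(values.size, -1, dtype=int)
    labels[finite] = lab_fin
    breaks = [float(sorted_vals[b - 1]) for b in bounds]
    return DiscretizationResult(labels=labels, k=int(k), gof=float(gof), breaks=breaks)
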