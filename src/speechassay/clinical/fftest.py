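"""Fasano-Franceschini two-sample test for 2-D point sets.

The multidimensional generalization of the Kolmogorov-Smirnov test: for each
sample point taken as an origin, the plane splits into four open quadrants
and the statistic is the largest discrepancy between the two samples'
empirical quadrant proportions, averaged over the two choices of origin
sample and scaled by sqrt(n1*n2/(n1+n2)). Significance is assessed by label
permutation, which is exact in distribution for exchangeable samples and
matches the small subgroup sizes this test is applied to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class FFResult:
    distance: float
    p_value: float
    n_perm: int
    n1: int
    n2: int


def _quadrant_masks(points: np.ndarray):
    """Boolean origin x point masks for the four open quadrants."""
    x, y = points[:, 0], points[:, 1]
    gx = x[None, :] > x[:, None]
    lx = x[None, :] < x[:, None]
    gy = y[None, :] > y[:, None]
    ly = y[None, :] < y[:, None]
    return (gx & gy, lx & gy, lx & ly, gx & ly)


def _ff_statistic(quadrants, labels_a: np.ndarray, n1: int, n2: int) -> float:
    """Max quadrant-proportion discrepancy, averaged over origin samples."""
    a = labels_a.astype(float)
    b = 1.0 - a
    d1 = 0.0  # origins in sample A
    d2 = 0.0  # origins in sample B
    for q in quadrants:
        fa = (q @ a) / n1
        fb = (q @ b) / n2
        diff = np.abs(fa - fb)
        d1 = max(d1, float(diff[labels_a].max(initial=0.0)))
        d2 = max(d2, float(diff[~labels_a].max(initial=0.0)))
    return 0.5 * (d1 + d2) * np.sqrt(n1 * n2 / (n1 + n2))


def ff_test(
    emb_a: np.ndarray,
    emb_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> FFResult:
    """Two-sample Fasano-Franceschini test on 2-D embeddings.

    Returns the scaled statistic and a permutation p-value
    ``(1 + #{perm >= observed}) / (n_perm + 1)``; deterministic given seed.
    """
    emb_a = np.asarray(emb_a, dtype=float)
    emb_b = np.asarray(emb_b, dtype=float)
    if emb_a.ndim != 2 or emb_a.shape[1] != 2 or emb_b.ndim != 2 or emb_b.shape[1] != 2:
        raise ValueError("embeddings must be 2-dimensional point sets")
    n1, n2 = emb_a.shape[0], emb_b.shape[0]
    if n1 < 3 or n2 < 3:
        raise ValueError("each sample needs at least 3 points")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is coarse")
    points = np.vstack([emb_a, emb_b])
    labels = np.zeros(n1 + n2, dtype=bool)
    labels[:n1] = True
    quadrants = _quadrant_masks(points)
    observed = _ff_statistic(quadrants, labels, n1, n2)
    rng = np.random.default_rng(seed)
    count = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _ff_statistic(quadrants, perm, n1, n2) >= observed - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return FFResult(distance=float(observed), p_value=float(p), n_perm=n_perm, n1=n1, n2=n2)
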