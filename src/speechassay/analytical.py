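"""Analytical validation: feature-vs-feature comparison of two pipelines.

Univariate: a full cross-set Spearman matrix with pairwise-complete deletion
and the study's strength bands (moderate |rho| > 0.50, strong > 0.70, very
strong > 0.90). Multivariate: sparse canonical correlation analysis via the
penalized matrix decomposition (PMD) — L1/L2-constrained rank-one power
iterations on X'Z with rank-one deflation for the second dimension — plus
loading extraction for biplots at the |0.50| substantial-loading threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STRENGTH_THRESHOLDS = (0.50, 0.70, 0.90)
LOADING_THRESHOLD = 0.50


@dataclass
class CorrelationReport:
    """Cross-set Spearman matrix with per-cell sample sizes and band counts."""

    rho: pd.DataFrame
    n_pairs: pd.DataFrame
    counts: dict
    thresholds: tuple = STRENGTH_THRESHOLDS

    @property
    def n_cells(self) -> int:
        return int(self.rho.size)


@dataclass
class SCCAResult:
    """Two-dimensional sparse CCA solution for a pair of feature views."""

    weights_A: pd.DataFrame  # features x 2
    weights_B: pd.DataFrame
    loadings_A: pd.DataFrame
    loadings_B: pd.DataFrame
    canonical_corrs: np.ndarray
    converged: tuple = (True, True)
    objective_trace: list = field(default_factory=list)


def spearman_matrix(table_a: pd.DataFrame, table_b: pd.DataFrame) -> CorrelationReport:
    """Spearman correlation of every column of ``table_a`` against every
    column of ``table_b`` (same recording rows), pairwise-complete, average
    ranks for ties. Cells with fewer than 4 complete pairs are NaN.
    """
    if not table_a.index.equals(table_b.index):
        raise ValueError("tables must be indexed by the same recordings")
    a = table_a.to_numpy(dtype=float)
    b = table_b.to_numpy(dtype=float)
    rho = np.full((a.shape[1], b.shape[1]), np.nan)
    npairs = np.zeros((a.shape[1], b.shape[1]), dtype=int)
    for i in range(a.shape[1]):
        ai = a[:, i]
        fin_a = np.isfinite(ai)
        for j in range(b.shape[1]):
            bj = b[:, j]
            ok = fin_a & np.isfinite(bj)
            n = int(ok.sum())
            npairs[i, j] = n
            if n < 4:
                continue
            if np.ptp(ai[ok]) == 0 or np.ptp(bj[ok]) == 0:
                continue
            rho[i, j] = stats.spearmanr(ai[ok], bj[ok]).statistic
    rho_df = pd.DataFrame(rho, index=table_a.columns, columns=table_b.columns)
    n_df = pd.DataFrame(npairs, index=table_a.columns, columns=table_b.columns)
    return CorrelationReport(rho=rho_df, n_pairs=n_df, counts=categorize_strengths(rho_df))


def categorize_strengths(rho_matrix) -> dict:
    """Count cells per strength band on |rho|.

    Bands follow the study's inequalities; a |rho| exactly on a boundary is
    assigned to the stronger band.
    """
    r = np.abs(np.asarray(rho_matrix, dtype=float)).ravel()
    r = r[np.isfinite(r)]
    mod, strong, very = STRENGTH_THRESHOLDS
    return {
        "moderate": int(np.sum((r > mod) & (r < strong))),
        "strong": int(np.sum((r >= strong) & (r < very))),
        "very_strong": int(np.sum(r >= very)),
    }


def _soft(x: np.ndarray, d: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - d, 0.0)


def _l1_projected(v: np.ndarray, c: float) -> np.ndarray:
    """Soft-threshold then L2-normalize so that ||out||_2 = 1, ||out||_1 <= c.

    The threshold is found by binary search (Witten-Tibshirani-Hastie PMD).
    """
    norm = np.linalg.norm(v)
    if norm == 0:
        return v
    u = v / norm
    if np.sum(np.abs(u)) <= c:
        return u
    lo, hi = 0.0, np.max(np.abs(v))
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        w = _soft(v, mid)
        nw = np.linalg.norm(w)
        if nw == 0:
            hi = mid
            continue
        if np.sum(np.abs(w)) / nw > c:
            lo = mid
        else:
            hi = mid
    w = _soft(v, hi)
    nw = np.linalg.norm(w)
    return w / nw if nw > 0 else w


def _pmd_rank_one(K: np.ndarray, c_a: float, c_b: float, tol: float, max_iter: int, rng):
    """One PMD factor: maximize u'Kv s.t. ||u||2<=1, ||v||2<=1, L1 bounds."""
    # initialize v from the leading right singular vector
    v = np.linalg.svd(K, full_matrices=False)[2][0]
    v = v / np.linalg.norm(v)
    trace = []
    converged = False
    for _ in range(max_iter):
        u = _l1_projected(K @ v, c_a)
        v_new = _l1_projected(K.T @ u, c_b)
        obj = float(u @ K @ v_new)
        if trace and obj < trace[-1] - 1e-8:
            warnings.warn("PMD objective decreased; numerical issue")
        delta = np.max(np.abs(v_new - v)) if v_new.size else 0.0
        trace.append(obj)
        v = v_new
        if delta < tol:
            converged = True
            break
    u = _l1_projected(K @ v, c_a)
    return u, v, trace, converged


def scca_pmd(
    X,
    Z,
    penalties: tuple | None = None,
    n_dims: int = 2,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> SCCAResult:
    """Sparse CCA of two standardized views by penalized matrix decomposition.

    ``penalties`` are the per-view L1 bounds (c_A, c_B), each within
    [1, sqrt(p)]; the default is 0.6*sqrt(p) per view. Successive dimensions
    come from rank-one deflation of X'Z. Canonical correlations are the
    Pearson correlations of the canonical variates; loadings are each
    feature's correlation with its view's variate. Outputs are sign-fixed so
    the largest-|weight| entry of each u is positive.
    """
    X = pd.DataFrame(X)
    Z = pd.DataFrame(Z)
    # drop features that are missing in half or more of the recordings
    # (task-inapplicable measures), then listwise-delete remaining rows
    for df in (X, Z):
        mostly_nan = [c for c in df.columns if df[c].isna().mean() >= 0.5]
        if mostly_nan:
            warnings.warn(f"dropping {len(mostly_nan)} mostly-missing column(s) before SCCA")
            df.drop(columns=mostly_nan, inplace=True)
    ok = np.isfinite(X.to_numpy(float)).all(axis=1) & np.isfinite(Z.to_numpy(float)).all(axis=1)
    Xv = X.loc[ok].to_numpy(float)
    Zv = Z.loc[ok].to_numpy(float)
    keep_a = Xv.std(axis=0) > 0
    keep_b = Zv.std(axis=0) > 0
    if not keep_a.all() or not keep_b.all():
        warnings.warn("dropping constant columns before SCCA")
    cols_a = X.columns[keep_a]
    cols_b = Z.columns[keep_b]
    Xv = Xv[:, keep_a]
    Zv = Zv[:, keep_b]
    Xs = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0)
    Zs = (Zv - Zv.mean(axis=0)) / Zv.std(axis=0)
    p, q = Xs.shape[1], Zs.shape[1]
    if penalties is None:
        penalties = (0.6 * np.sqrt(p), 0.6 * np.sqrt(q))
    c_a = float(np.clip(penalties[0], 1.0, np.sqrt(p)))
    c_b = float(np.clip(penalties[1], 1.0, np.sqrt(q)))
    rng = np.random.default_rng(seed)

    K = Xs.T @ Zs
    us, vs, traces, convs = [], [], [], []
    for _ in range(n_dims):
        u, v, trace, conv = _pmd_rank_one(K, c_a, c_b, tol, max_iter, rng)
        if not conv:
            warnings.warn("PMD did not converge within max_iter")
        # sign convention
        iu = int(np.argmax(np.abs(u)))
        if u[iu] < 0:
            u, v = -u, -v
        us.append(u)
        vs.append(v)
        traces.append(trace)
        convs.append(conv)
        K = K - (u @ K @ v) * np.outer(u, v)

    U = np.column_stack(us)
    V = np.column_stack(vs)
    scores_a = Xs @ U
    scores_b = Zs @ V
    ccorr = np.array(
        [
            np.corrcoef(scores_a[:, k], scores_b[:, k])[0, 1]
            if scores_a[:, k].std() > 0 and scores_b[:, k].std() > 0
            else np.nan
            for k in range(n_dims)
        ]
    )

    def _loadings(data, scores):
        L = np.zeros((data.shape[1], n_dims))
        for k in range(n_dims):
            s = scores[:, k]
            if s.std() == 0:
                L[:, k] = np.nan
                continue
            sc = (s - s.mean()) / s.std()
            L[:, k] = data.T @ sc / data.shape[0]
        return L

    dims = [f"dim{k + 1}" for k in range(n_dims)]
    return SCCAResult(
        weights_A=pd.DataFrame(U, index=cols_a, columns=dims),
        weights_B=pd.DataFrame(V, index=cols_b, columns=dims),
        loadings_A=pd.DataFrame(_loadings(Xs, scores_a), index=cols_a, columns=dims),
        loadings_B=pd.DataFrame(_loadings(Zs, scores_b), index=cols_b, columns=dims),
        canonical_corrs=ccorr,
        converged=tuple(convs),
        objective_trace=traces,
    )


def biplot_data(result: SCCAResult, loading_threshold: float = LOADING_THRESHOLD) -> pd.DataFrame:
    """Biplot coordinates: features whose |loading| exceeds the threshold on
    at least one of the two dimensions, with their view label."""
    if result.loadings_A.shape[1] != 2:
        raise ValueError("biplot requires a 2-dimensional SCCA result")
    rows = []
    for view, loadings in (("A", result.loadings_A), ("B", result.loadings_B)):
        for name, (x, y) in loadings.iterrows():
            if max(abs(x), abs(y)) > loading_threshold:
                rows.append({"feature": name, "view": view, "dim1": x, "dim2": y})
    return pd.DataFrame(rows, columns=["feature", "view", "dim1", "dim2"])
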