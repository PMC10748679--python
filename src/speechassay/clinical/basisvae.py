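"""BasisVAE: interpretable feature clustering with a variational autoencoder.

Model. Each participant's standardized feature vector x_i (p features) is
encoded to a 2-dimensional Gaussian posterior q(z_i) = N(mu_i, diag(var_i)).
The decoder produces K <= max_clusters shared basis functions b_k(z) (a small
MLP of the latent), and every feature j reconstructs as a feature-specific
affine transform of ONE basis function: x_ij ~ N(lambda_j b_k(z_i) + delta_j,
sigma_j^2), with a categorical variational posterior phi_jk over the
assignment k. The evidence lower bound is

    sum_ijk phi_jk [ -(x_ij - lambda_j b_k(z_i) - delta_j)^2 / (2 sigma_j^2) ]
    - n/2 sum_j log sigma_j^2  - sum_i KL(q(z_i) || N(0, I))
    - sum_jk phi_jk log(phi_jk / pi_k)

Optimization alternates a reparameterized Adam step on the encoder/decoder
networks with closed-form coordinate updates for lambda, delta, sigma^2,
phi and the mixture weights pi. phi updates are temperature-annealed (soft
early, sharp late) to avoid premature hard assignment, and pi uses a
sparsifying Dirichlet(alpha < 1) MAP update, which lets redundant clusters
empty out — requesting more clusters than the data supports then yields
empty clusters rather than split ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass
class BasisVAEConfig:
    max_clusters: int = 3
    latent_dim: int = 2
    hidden: int = 32
    epochs: int = 2000
    learning_rate: float = 1e-3
    prior_alpha: float = 0.1  # Dirichlet concentration for pi (< 1 sparsifies)
    anneal_frac: float = 0.5  # fraction of epochs over which tau: 5 -> 1
    kl_warmup_frac: float = 0.2
    n_restarts: int = 2
    sigma_floor: float = 0.1
    grad_clip: float = 5.0


@dataclass
class BasisVAEOutputs:
    """Embeddings, feature-cluster probabilities and feature predictions."""

    embeddings: pd.DataFrame  # participants x latent_dim (posterior means)
    cluster_probs: pd.DataFrame  # features x clusters, rows sum to 1
    predictions: pd.DataFrame  # participants x features, original scale
    n_clusters_effective: int
    elbo: float
    config: BasisVAEConfig = field(default_factory=BasisVAEConfig)
    dropped_features: list = field(default_factory=list)

    def hard_assignments(self) -> pd.Series:
        return self.cluster_probs.idxmax(axis=1)


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1**self.t)
            vh = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + eps)


def _init_params(rng, p, hidden, latent, K):
    def glorot(a, b):
        return rng.normal(0.0, np.sqrt(2.0 / (a + b)), (a, b))

    return {
        "W1": glorot(p, hidden),
        "b1": np.zeros(hidden),
        "W_mu": glorot(hidden, latent),
        "b_mu": np.zeros(latent),
        "W_lv": glorot(hidden, latent),
        "b_lv": np.zeros(latent),
        "V1": glorot(latent, hidden),
        "c1": np.zeros(hidden),
        "V2": glorot(hidden, K),
        "c2": np.zeros(K),
    }


def _encode(params, X):
    h = np.tanh(X @ params["W1"] + params["b1"])
    mu = h @ params["W_mu"] + params["b_mu"]
    logvar = np.clip(h @ params["W_lv"] + params["b_lv"], -8.0, 8.0)
    return h, mu, logvar


def _decode(params, z):
    """Decoder with per-column basis normalization.

    Raw MLP outputs are standardized per basis column (zero mean, unit
    variance over the batch), which pins the scale ambiguity between the
    shared basis functions and the per-feature scales lambda_j and keeps
    both the gradients and the coordinate updates well conditioned.
    """
    g = np.tanh(z @ params["V1"] + params["c1"])
    b_raw = g @ params["V2"] + params["c2"]
    b_mean = b_raw.mean(axis=0)
    b_std = b_raw.std(axis=0) + 1e-6
    return g, (b_raw - b_mean) / b_std, b_std


def _fit_once(X, cfg: BasisVAEConfig, seed: int):
    n, p = X.shape
    K = cfg.max_clusters
    rng = np.random.default_rng(seed)
    params = _init_params(rng, p, cfg.hidden, cfg.latent_dim, K)
    opt = _Adam(params, cfg.learning_rate)

    # assignment init: k-means on the feature-feature |correlation| profile
    # breaks the label symmetry that random initialization cannot
    corr = np.abs(np.corrcoef(X.T))
    corr[~np.isfinite(corr)] = 0.0
    km = KMeans(n_clusters=K, n_init=4, random_state=int(rng.integers(2**31)))
    hard0 = km.fit_predict(corr)
    phi = np.full((p, K), 0.05 / max(K - 1, 1))
    phi[np.arange(p), hard0] = 0.95
    phi /= phi.sum(axis=1, keepdims=True)
    pi = np.full(K, 1.0 / K)

    # warmup targets: each initial cluster's leading principal-component
    # score, so the basis functions start as the group response profiles
    targets = np.zeros((n, K))
    for k in range(K):
        cols = np.flatnonzero(hard0 == k)
        if cols.size == 0:
            continue
        sub = X[:, cols]
        uu, ss, vv = np.linalg.svd(sub - sub.mean(axis=0), full_matrices=False)
        score = uu[:, 0] * ss[0]
        if score.std() > 0:
            score = score / score.std()
        if np.corrcoef(score, sub.mean(axis=1))[0, 1] < 0:
            score = -score
        targets[:, k] = score
    lam = np.ones(p)
    delta = np.zeros(p)
    sigma2 = np.ones(p)

    anneal_epochs = max(1, int(cfg.anneal_frac * cfg.epochs))
    warmup = max(1, int(cfg.kl_warmup_frac * cfg.epochs))

    for epoch in range(cfg.epochs):
        tau = max(1.0, 5.0 - 4.0 * epoch / anneal_epochs)
        beta = min(1.0, epoch / warmup)
        if epoch == warmup:  # fresh optimizer state for the ELBO phase
            opt = _Adam(params, cfg.learning_rate)

        # --- network step (sampled z, reparameterized) ---
        h, mu, logvar = _encode(params, X)
        eps = rng.standard_normal(mu.shape)
        std = np.exp(0.5 * logvar)
        z = mu + eps * std
        g, B, b_std = _decode(params, z)

        resid = X[:, :, None] - lam[None, :, None] * B[:, None, :] - delta[None, :, None]
        loss_recon = float(np.sum(phi[None] * resid**2 / (2 * sigma2[None, :, None])))
        loss_kl = 0.5 * float(np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar))
        if not np.isfinite(loss_recon + loss_kl):
            raise RuntimeError(
                f"non-finite BasisVAE loss at epoch {epoch} (seed={seed}, cfg={cfg})"
            )

        # gradient of recon loss wrt basis values B (n x K); during warmup
        # the basis is regressed onto its cluster's PC score instead
        if epoch < warmup:
            dB = B - targets
        else:
            w = phi * (lam / sigma2)[:, None]  # p x K
            dB = -np.einsum("ijk,jk->ik", resid, w)
        # backprop through the basis normalization, then the decoder MLP
        dB = (dB - dB.mean(axis=0) - B * (dB * B).mean(axis=0)) / b_std
        dV2 = g.T @ dB
        dc2 = dB.sum(axis=0)
        dg = dB @ params["V2"].T
        dpre = dg * (1.0 - g * g)
        dV1 = z.T @ dpre
        dc1 = dpre.sum(axis=0)
        dz = dpre @ params["V1"].T
        # encoder backprop through the reparameterization + KL
        dmu = dz + beta * mu
        dlogvar = dz * eps * 0.5 * std + beta * 0.5 * (np.exp(logvar) - 1.0)
        dW_mu = h.T @ dmu
        db_mu = dmu.sum(axis=0)
        dW_lv = h.T @ dlogvar
        db_lv = dlogvar.sum(axis=0)
        dh = dmu @ params["W_mu"].T + dlogvar @ params["W_lv"].T
        dpre_h = dh * (1.0 - h * h)
        grads = {
            "W1": X.T @ dpre_h,
            "b1": dpre_h.sum(axis=0),
            "W_mu": dW_mu,
            "b_mu": db_mu,
            "W_lv": dW_lv,
            "b_lv": db_lv,
            "V1": dV1,
            "c1": dc1,
            "V2": dV2,
            "c2": dc2,
        }
        for k in grads:  # per-sample scaling plus norm clipping for stability
            g = grads[k] / n
            gn = np.linalg.norm(g)
            if gn > cfg.grad_clip:
                g = g * (cfg.grad_clip / gn)
            grads[k] = g
        opt.step(params, grads)

        # --- coordinate updates on deterministic, normalized basis values ---
        _, mu, _ = _encode(params, X)
        _, Bm, _ = _decode(params, mu)
        # with zero-mean/unit-variance basis columns the weighted least
        # squares for (lambda_j, delta_j) becomes diagonal
        C = X.T @ Bm  # p x K
        lam = (phi * C).sum(axis=1) / n
        delta = X.mean(axis=0)

        resid_m = X[:, :, None] - lam[None, :, None] * Bm[:, None, :] - delta[None, :, None]
        E = np.sum(resid_m**2, axis=0)  # p x K
        sigma2 = np.maximum((phi * E).sum(axis=1) / n, cfg.sigma_floor**2)
        if epoch >= warmup:  # hold assignments while the decoder warms up
            logphi = (
                np.log(np.maximum(pi, 1e-12))[None, :] - E / (2 * sigma2[:, None])
            ) / tau
            logphi -= logphi.max(axis=1, keepdims=True)
            phi = np.exp(logphi)
            phi /= phi.sum(axis=1, keepdims=True)
            mass = phi.sum(axis=0) + cfg.prior_alpha - 1.0
            pi = np.maximum(mass, 1e-12)
            pi /= pi.sum()

    # final ELBO (deterministic z = mu)
    _, mu, logvar = _encode(params, X)
    _, Bm, _ = _decode(params, mu)
    resid_m = X[:, :, None] - lam[None, :, None] * Bm[:, None, :] - delta[None, :, None]
    E = np.sum(resid_m**2, axis=0)
    n_ = X.shape[0]
    recon = -float(np.sum(phi * E / (2 * sigma2[:, None]))) - 0.5 * n_ * float(
        np.sum(np.log(sigma2))
    )
    kl_z = 0.5 * float(np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar))
    kl_phi = float(
        np.sum(phi * (np.log(np.maximum(phi, 1e-12)) - np.log(np.maximum(pi, 1e-12))))
    )
    elbo = recon - kl_z - kl_phi
    preds_std = np.einsum("jk,ik->ij", phi * lam[:, None], Bm) + delta[None, :]
    return elbo, mu, phi, preds_std


def train_basisvae(
    features: pd.DataFrame,
    max_clusters: int = 3,
    latent_dim: int = 2,
    seed: int = 0,
    config: BasisVAEConfig | None = None,
) -> BasisVAEOutputs:
    """Train BasisVAE on a participants x features table.

    Columns containing missing values are removed before training (they
    cannot enter the reconstruction likelihood); remaining columns are
    standardized internally and predictions are returned on the original
    scale. The best of ``config.n_restarts`` differently-initialized runs by
    final ELBO is returned. Clusters to which no feature is assigned
    (argmax) leave ``n_clusters_effective`` below ``max_clusters``.
    """
    cfg = config or BasisVAEConfig()
    cfg.max_clusters = max_clusters
    cfg.latent_dim = latent_dim

    dropped = [c for c in features.columns if features[c].isna().any()]
    if dropped:
        warnings.warn(f"removing {len(dropped)} feature(s) with missing values")
    data = features.drop(columns=dropped)
    if data.shape[0] < 20:
        warnings.warn(f"only {data.shape[0]} participants; results may be unstable")
    X = data.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd

    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(max(1, cfg.n_restarts)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        result = _fit_once(Xs, cfg, sub_seed)
        if best is None or result[0] > best[0]:
            best = result
    elbo, mu, phi, preds_std = best

    preds = preds_std * sd[None, :] + mean[None, :]
    clusters = [f"cluster{k + 1}" for k in range(cfg.max_clusters)]
    dims = [f"dim{d + 1}" for d in range(cfg.latent_dim)]
    cluster_probs = pd.DataFrame(phi, index=data.columns, columns=clusters)
    n_eff = int(cluster_probs.idxmax(axis=1).nunique())
    return BasisVAEOutputs(
        embeddings=pd.DataFrame(mu, index=data.index, columns=dims),
        cluster_probs=cluster_probs,
        predictions=pd.DataFrame(preds, index=data.index, columns=data.columns),
        n_clusters_effective=n_eff,
        elbo=float(elbo),
        config=cfg,
        dropped_features=dropped,
    )
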