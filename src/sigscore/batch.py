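"""Empirical-Bayes batch adjustment and the guided-PCA batch-bias test.

``combat_fit_transform`` implements the parametric ComBat model without
covariates: genes are standardized against their grand mean and pooled
variance, per-batch location and scale estimates are shrunk toward
moment-matched normal / inverse-gamma priors by iterating the EB posterior
means, and the data are back-transformed.  ``gpca_test`` asks whether batch
labels explain the dominant variance axis: the delta statistic compares the
variance captured by the first batch-guided principal component to that of
the first unguided one, with significance from batch-label permutations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionCompendium, SigscoreError

logger = logging.getLogger(__name__)


@dataclass
class BatchModel:
    """Fitted parametric ComBat parameters (genes × batches where 2-D)."""

    grand_mean: pd.Series
    pooled_sd: pd.Series
    gamma_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta2_hat: pd.DataFrame
    delta2_star: pd.DataFrame
    gamma_bar: pd.Series
    tau2_bar: pd.Series
    a_prior: pd.Series
    b_prior: pd.Series
    n_iterations: dict[str, int] | None = None


@dataclass(frozen=True)
class GPCAResult:
    """Guided-PCA batch-bias test result."""

    delta: float
    p_value: float
    n_permutations: int
    pc1_variance_share: float
    pc2_variance_share: float


def _batch_series(c: ExpressionCompendium, batches) -> pd.Series:
    """Resolve per-array batch labels from a sample table, Series or the compendium."""
    if batches is None:
        if c.batches is None:
            raise SigscoreError("no batch labels available")
        b = c.batches
    elif isinstance(batches, pd.DataFrame):
        b = batches.set_index("array_id")["batch"]
    else:
        b = pd.Series(batches)
    b = b.reindex(c.array_ids)
    if b.isna().any():
        missing = b.index[b.isna()]
        raise SigscoreError(f"arrays missing a batch label: {list(missing[:5])}")
    return b.astype(str)


def combat_fit_transform(
    c: ExpressionCompendium,
    batches: pd.DataFrame | pd.Series | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[ExpressionCompendium, BatchModel]:
    """Remove additive and multiplicative batch effects (parametric EB).

    Steps: (1) gene-standardize with the grand mean (batch-size-weighted mean
    of batch means) and the pooled residual variance; (2) per-batch location
    γ̂ and scale δ̂² estimates on the standardized data; (3) normal and
    inverse-gamma hyperpriors moment-matched across genes; (4) coordinate
    iteration of the EB posterior means to ``tol`` on the max relative change
    (cap ``max_iter``); (5) back-transform.

    A single-batch input is returned unchanged.  Zero-variance genes pass
    through unadjusted with a warning; a batch with fewer than two arrays is
    a hard error.
    """
    b = _batch_series(c, batches)
    levels = list(dict.fromkeys(b))
    if len(levels) == 1:
        logger.info("combat: single batch, returning input unchanged")
        model = _trivial_model(c, levels)
        return ExpressionCompendium(c.values.copy(), c.features.copy(), c.cohort, b), model
    sizes = b.value_counts()
    singletons = sizes[sizes < 2]
    if len(singletons):
        raise SigscoreError(f"singleton batch(es): {list(singletons.index)}")

    X = c.values.to_numpy(dtype=float)
    masks = {lvl: (b == lvl).to_numpy() for lvl in levels}
    n_genes = X.shape[0]

    # per-batch means and counts (NaN-aware)
    batch_mean = np.empty((n_genes, len(levels)))
    batch_n = np.empty((n_genes, len(levels)))
    for j, lvl in enumerate(levels):
        sub = X[:, masks[lvl]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            batch_mean[:, j] = np.nanmean(sub, axis=1)
        batch_n[:, j] = np.isfinite(sub).sum(axis=1)
    if (batch_n == 0).any():
        raise SigscoreError("gene entirely missing within a batch")

    n_total = batch_n.sum(axis=1)
    grand_mean = (batch_mean * batch_n).sum(axis=1) / n_total
    fitted = np.empty_like(X)
    for j, lvl in enumerate(levels):
        fitted[:, masks[lvl]] = batch_mean[:, [j]]
    resid = X - fitted
    pooled_var = np.nansum(resid**2, axis=1) / n_total  # sva convention: /N
    zero_var = pooled_var <= 0
    if zero_var.any():
        logger.warning("combat: %d zero-variance genes passed through unadjusted",
                       int(zero_var.sum()))
    safe_var = np.where(zero_var, 1.0, pooled_var)
    pooled_sd = np.sqrt(safe_var)

    Z = (X - grand_mean[:, None]) / pooled_sd[:, None]

    gamma_hat = np.empty((n_genes, len(levels)))
    delta2_hat = np.empty((n_genes, len(levels)))
    for j, lvl in enumerate(levels):
        sub = Z[:, masks[lvl]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gamma_hat[:, j] = np.nanmean(sub, axis=1)
            delta2_hat[:, j] = np.nanvar(sub, axis=1, ddof=1)

    gamma_bar = gamma_hat.mean(axis=0)
    tau2_bar = gamma_hat.var(axis=0, ddof=1)
    a_prior = np.empty(len(levels))
    b_prior = np.empty(len(levels))
    m_prior = delta2_hat.mean(axis=0)
    # size-weighted mean scale across batches; reference point for the
    # degenerate (zero cross-gene spread) prior so that scale-homogeneous
    # batches are left untouched
    batch_sizes = np.array([masks[lvl].sum() for lvl in levels], dtype=float)
    m_pooled = float(np.sum(batch_sizes * m_prior) / batch_sizes.sum())
    for j in range(len(levels)):
        m = m_prior[j]
        s2 = delta2_hat[:, j].var(ddof=1)
        if s2 <= 1e-12 * max(m**2, 1e-300):  # degenerate: all genes share one scale
            a_prior[j] = np.inf
            b_prior[j] = m / m_pooled
        else:
            a_prior[j] = (2 * s2 + m**2) / s2
            b_prior[j] = (m * s2 + m**3) / s2

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    n_iter: dict[str, int] = {}
    for j, lvl in enumerate(levels):
        sub = Z[:, masks[lvl]]
        n_j = batch_n[:, j]
        g_old = gamma_hat[:, j].copy()
        d_old = delta2_hat[:, j].copy()
        for it in range(1, max_iter + 1):
            if np.isinf(a_prior[j]):
                g_new = gamma_hat[:, j] if tau2_bar[j] > 0 else np.full(n_genes, gamma_bar[j])
                d_new = np.full(n_genes, b_prior[j])
                if tau2_bar[j] > 0:
                    g_new = (n_j * tau2_bar[j] * gamma_hat[:, j] + d_new * gamma_bar[j]) / (
                        n_j * tau2_bar[j] + d_new
                    )
            else:
                g_new = (n_j * tau2_bar[j] * gamma_hat[:, j] + d_old * gamma_bar[j]) / (
                    n_j * tau2_bar[j] + d_old
                )
                sse = np.nansum((sub - g_new[:, None]) ** 2, axis=1)
                d_new = (0.5 * sse + b_prior[j]) / (n_j / 2.0 + a_prior[j] - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        n_iter[lvl] = it
        gamma_star[:, j] = g_old
        delta2_star[:, j] = d_old

    adjusted = np.empty_like(Z)
    for j, lvl in enumerate(levels):
        adjusted[:, masks[lvl]] = (Z[:, masks[lvl]] - gamma_star[:, [j]]) / np.sqrt(
            delta2_star[:, [j]]
        )
    adjusted = adjusted * pooled_sd[:, None] + grand_mean[:, None]
    adjusted[zero_var, :] = X[zero_var, :]

    genes = c.values.index
    model = BatchModel(
        grand_mean=pd.Series(grand_mean, index=genes),
        pooled_sd=pd.Series(np.where(zero_var, 0.0, pooled_sd), index=genes),
        gamma_hat=pd.DataFrame(gamma_hat, index=genes, columns=levels),
        gamma_star=pd.DataFrame(gamma_star, index=genes, columns=levels),
        delta2_hat=pd.DataFrame(delta2_hat, index=genes, columns=levels),
        delta2_star=pd.DataFrame(delta2_star, index=genes, columns=levels),
        gamma_bar=pd.Series(gamma_bar, index=levels),
        tau2_bar=pd.Series(tau2_bar, index=levels),
        a_prior=pd.Series(a_prior, index=levels),
        b_prior=pd.Series(b_prior, index=levels),
        n_iterations=n_iter,
    )
    out = ExpressionCompendium(
        pd.DataFrame(adjusted, index=genes, columns=c.values.columns),
        c.features.copy(),
        c.cohort,
        b,
    )
    return out, model


def _trivial_model(c: ExpressionCompendium, levels: list[str]) -> BatchModel:
    genes = c.values.index
    zeros = pd.DataFrame(0.0, index=genes, columns=levels)
    ones = pd.DataFrame(1.0, index=genes, columns=levels)
    return BatchModel(
        grand_mean=c.values.mean(axis=1),
        pooled_sd=c.values.std(axis=1, ddof=0),
        gamma_hat=zeros.copy(),
        gamma_star=zeros.copy(),
        delta2_hat=ones.copy(),
        delta2_star=ones.copy(),
        gamma_bar=pd.Series(0.0, index=levels),
        tau2_bar=pd.Series(0.0, index=levels),
        a_prior=pd.Series(np.inf, index=levels),
        b_prior=pd.Series(1.0, index=levels),
    )


# ---------------------------------------------------------------------------
# guided PCA
# ---------------------------------------------------------------------------

def _gpca_delta(Xc: np.ndarray, onehot: np.ndarray, denom: float) -> float:
    """delta for centered samples × genes data and a 0/1 batch indicator."""
    _, _, vt = np.linalg.svd(onehot.T @ Xc, full_matrices=False)
    guided_scores = Xc @ vt[0]
    return float(np.var(guided_scores) / denom)


def gpca_test(
    c: ExpressionCompendium,
    batches: pd.DataFrame | pd.Series | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> GPCAResult:
    """Permutation test of batch bias via guided principal components.

    delta = var(scores on PC1 of batchᵀ·X) / var(scores on PC1 of X), on
    sample-space data centered gene-wise (missing spots replaced by the gene
    mean, i.e. zero after centering).  The p-value is the add-one-corrected
    fraction of batch-label permutations with delta at least the observed.
    """
    b = _batch_series(c, batches)
    levels = sorted(set(b))
    if len(levels) < 2:
        raise SigscoreError("gpca_test requires >= 2 batches")
    if n_perm < 100:
        raise SigscoreError("n_perm must be >= 100")

    X = c.values.to_numpy(dtype=float).T  # samples × genes
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isfinite(X), X, col_mean[None, :])
    Xc = X - X.mean(axis=0, keepdims=True)

    _, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var_shares = s**2 / np.sum(s**2)
    # variance of scores on unguided PC1: s1^2 / n (ddof 0, centered scores)
    denom = float(s[0] ** 2 / Xc.shape[0])

    codes = pd.Categorical(b, categories=levels).codes
    onehot = np.eye(len(levels))[codes]
    delta_obs = _gpca_delta(Xc, onehot, denom)

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(codes))
        if _gpca_delta(Xc, onehot[perm], denom) >= delta_obs:
            n_ge += 1
    p = (n_ge + 1) / (n_perm + 1)
    return GPCAResult(
        delta=delta_obs,
        p_value=float(p),
        n_permutations=n_perm,
        pc1_variance_share=float(var_shares[0]),
        pc2_variance_share=float(var_shares[1]) if len(var_shares) > 1 else 0.0,
    )
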