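"""Within-cluster probability model for covariate profiles.

Nominal covariates follow a cluster-specific multinomial with a conjugate
Dirichlet prior. Ordinal covariates follow an ordered-threshold construction:
strictly increasing cutpoints lambda_1 < ... < lambda_{M-1} partition a latent
standard normal, and category j has probability
Phi(lambda_{j+1}) - Phi(lambda_j) with lambda_0 = -inf, lambda_M = +inf.
Only the ordering of categories is imposed; the induced category probabilities
are otherwise free, and the prior used here is uniform on the induced
probability simplex (i.e. Dirichlet(1, ..., 1) pushed through the cutpoint
map), under which the cutpoints have density proportional to the product of
standard-normal pdfs on the ordered region.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri, xlogy

from .data import MISSING, ORDINAL, CovariateSpec

__all__ = [
    "ordinal_probs",
    "probs_to_thresholds",
    "profile_loglik",
    "sample_phi_posterior",
    "update_thresholds",
    "threshold_log_target",
]


def ordinal_probs(thresholds: np.ndarray, M: int | None = None) -> np.ndarray:
    """Category probabilities induced by ordered standard-normal cutpoints.

    Parameters
    ----------
    thresholds : array of shape (M-1,) or (K, M-1)
        Strictly increasing along the last axis.
    M : int, optional
        Number of categories; checked against the threshold count if given.

    Returns
    -------
    probs : array of shape (..., M)
        ``(Phi(l_1), Phi(l_2)-Phi(l_1), ..., 1-Phi(l_{M-1}))``.
    """
    lam = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if M is not None and lam.shape[-1] != M - 1:
        raise ValueError(f"expected {M - 1} thresholds, got {lam.shape[-1]}")
    if np.any(np.diff(lam, axis=-1) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    cdf = ndtr(lam)
    pad = np.broadcast_to
    lo = np.concatenate([np.zeros(lam.shape[:-1] + (1,)), cdf], axis=-1)
    hi = np.concatenate([cdf, np.ones(lam.shape[:-1] + (1,))], axis=-1)
    out = hi - lo
    return out if np.asarray(thresholds).ndim > 1 else out.reshape(-1)


def probs_to_thresholds(p: np.ndarray) -> np.ndarray:
    """Inverse of :func:`ordinal_probs` on the interior of the simplex.

    ``lambda_j = Phi^{-1}(p_0 + ... + p_{j-1})``; requires every category
    probability strictly positive (coincident cutpoints otherwise).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("zero-probability category: thresholds would coincide")
    if np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-8):
        raise ValueError("probabilities must sum to 1")
    cum = np.cumsum(p[..., :-1], axis=-1)
    return ndtri(np.clip(cum, 1e-15, 1 - 1e-15))


def cluster_category_probs(phi: dict, specs: list[CovariateSpec]) -> list[np.ndarray]:
    """Materialise per-covariate category-probability vectors for one cluster.

    ``phi`` maps covariate index -> probability vector (nominal) or
    threshold vector (ordinal, detected from specs).
    """
    out = []
    for p, spec in enumerate(specs):
        v = np.asarray(phi[p], dtype=float)
        if spec.kind == ORDINAL and v.shape[-1] == spec.n_categories - 1:
            v = ordinal_probs(v, spec.n_categories)
        out.append(v)
    return out


def profile_loglik(x: np.ndarray, cluster_params, specs: list[CovariateSpec]) -> float:
    """Log-likelihood of one covariate profile under one cluster's parameters.

    Missing entries (:data:`MISSING`) contribute zero — imputation inside the
    sampler completes them; this marginalised form serves diagnostics.

    ``cluster_params`` is a sequence (or index->vector mapping) giving, per
    covariate, either a category-probability vector or, for ordinal
    covariates, a threshold vector.
    """
    x = np.asarray(x)
    probs = cluster_category_probs(cluster_params, specs)
    total = 0.0
    for p, spec in enumerate(specs):
        xi = int(x[p])
        if xi == MISSING:
            continue
        if xi < 0 or xi >= spec.n_categories:
            raise ValueError(f"covariate {spec.name!r}: category {xi} out of "
                             f"range 0..{spec.n_categories - 1}")
        total += float(np.log(probs[p][xi]))
    return total


def sample_phi_posterior(counts: np.ndarray, prior: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """One draw from the conjugate Dirichlet posterior ``Dir(prior + counts)``.

    Supports a batch leading axis on ``counts`` (one row per cluster).
    """
    counts = np.asarray(counts, dtype=float)
    prior = np.asarray(prior, dtype=float)
    if np.any(counts < 0) or np.any(prior <= 0):
        raise ValueError("counts must be >= 0 and prior > 0")
    alpha = counts + prior
    g = rng.gamma(alpha)
    # guard against all-zero rows at extreme small alpha
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=-1, keepdims=True)


def threshold_log_target(thresholds: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Unnormalised log posterior of ordinal cutpoints given category counts.

    Prior: uniform on the induced probability simplex, whose pullback on the
    ordered cutpoint region has density prod_j phi(lambda_j) (standard-normal
    pdf). Likelihood: multinomial in the induced category probabilities.
    Batched over a leading cluster axis.
    """
    lam = np.asarray(thresholds, dtype=float)
    counts = np.asarray(counts, dtype=float)
    probs = ordinal_probs(lam)
    if lam.ndim == 1:
        probs = probs.reshape(1, -1)
        lam2 = lam.reshape(1, -1)
        counts = counts.reshape(1, -1)
    else:
        lam2 = lam
    logp = -0.5 * (lam2 ** 2) - 0.5 * np.log(2 * np.pi)
    out = logp.sum(axis=-1) + xlogy(counts, probs).sum(axis=-1)
    return out if np.asarray(thresholds).ndim > 1 else float(out[0])


def update_thresholds(current: np.ndarray, category_counts: np.ndarray,
                      proposal_scale, rng: np.random.Generator):
    """Random-walk Metropolis sweep over the interior cutpoints.

    One Gaussian random-walk proposal per cutpoint, in index order; proposals
    violating the strict ordering are rejected outright (the proposal is
    symmetric, so the acceptance ratio is the posterior ratio). Batched over a
    leading cluster axis: ``current`` of shape (K, M-1) with ``category_counts``
    of shape (K, M) updates all clusters at once.

    Parameters
    ----------
    proposal_scale : float or array broadcastable to (K, M-1)
        Standard deviation of the random walk. A scale of exactly 0 leaves the
        state unchanged and counts as accepted.

    Returns
    -------
    thresholds : ndarray, same shape as ``current``
    accepted : ndarray of bool, same shape (per-cutpoint acceptance)
    """
    lam = np.array(current, dtype=float, copy=True)
    single = lam.ndim == 1
    if single:
        lam = lam.reshape(1, -1)
        category_counts = np.asarray(category_counts).reshape(1, -1)
    K, J = lam.shape
    scale = np.broadcast_to(np.asarray(proposal_scale, dtype=float), (K, J))
    accepted = np.zeros((K, J), dtype=bool)
    cur_lp = np.atleast_1d(threshold_log_target(lam, category_counts))
    # a numerically degenerate current state (underflowed category) must not
    # pin the chain: treat it as arbitrarily unlikely instead of -inf
    cur_lp = np.where(np.isneginf(cur_lp), -1e300, cur_lp)
    for j in range(J):
        step = scale[:, j] * rng.standard_normal(K)
        prop = lam.copy()
        prop[:, j] = lam[:, j] + step
        zero = scale[:, j] == 0.0
        lo = prop[:, j - 1] if j > 0 else np.full(K, -np.inf)
        hi = prop[:, j + 1] if j < J - 1 else np.full(K, np.inf)
        valid = (prop[:, j] > lo) & (prop[:, j] < hi)
        new_lp = np.where(valid, 0.0, -np.inf)
        if valid.any():
            lp = threshold_log_target(prop[valid], category_counts[valid])
            new_lp[valid] = np.atleast_1d(lp)
        logu = np.log(rng.random(K))
        acc = valid & (logu < new_lp - cur_lp)
        acc = np.where(zero, True, acc)  # degenerate proposal: state unchanged
        move = acc & ~zero
        lam[move, j] = prop[move, j]
        cur_lp = np.where(move, new_lp, cur_lp)
        accepted[:, j] = acc
    if single:
        return lam.reshape(-1), accepted.reshape(-1)
    return lam, accepted
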