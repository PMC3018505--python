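"""Disease submodel: per-cluster association with the binary outcome.

In *plain* mode each cluster k carries a risk theta_k on the probability
scale, P(y_i = 1) = theta_k for every subject allocated to k, with a conjugate
Beta prior. In *logistic* mode theta_k is the cluster's baseline log-odds and
confounders enter additively, logit P(y_i = 1) = beta . w_i + theta_k, so
expit(theta_k) is the risk of a subject with all confounders at their
reference value of zero. A prospective Bernoulli likelihood is used throughout
(appropriate for case-control data with categorical exposures and
noninformative priors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["outcome_loglik", "sample_theta_plain", "update_theta_beta_logistic"]

PLAIN = "plain"
LOGISTIC = "logistic"


def outcome_loglik(y, theta_k, w=None, beta=None, mode: str = PLAIN):
    """Bernoulli log-likelihood of outcome(s) under one cluster's parameters.

    Parameters
    ----------
    y : 0/1 scalar or array
    theta_k : float
        Risk in (0,1) (plain) or baseline log-odds (logistic).
    w, beta : arrays, optional
        Confounder values and coefficients (logistic mode only).
    """
    y = np.asarray(y, dtype=float)
    if mode == PLAIN:
        if w is not None and np.size(w):
            raise ValueError("plain mode admits no confounders")
        if not 0.0 < theta_k < 1.0:
            raise ValueError(f"plain-mode theta must lie in (0,1), got {theta_k}")
        p = theta_k
    elif mode == LOGISTIC:
        eta = float(theta_k)
        if w is not None and beta is not None and np.size(w):
            eta = eta + float(np.dot(np.asarray(beta, float), np.asarray(w, float)))
        p = expit(eta)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ll = y * np.log(p) + (1.0 - y) * np.log1p(-p)
    return float(ll) if ll.ndim == 0 else ll


def sample_theta_plain(case_count, total, prior=(1.0, 1.0),
                       rng: np.random.Generator | None = None):
    """Conjugate draw theta ~ Beta(a + cases, b + controls).

    Vectorised over clusters when ``case_count``/``total`` are arrays; empty
    clusters (total 0) simply draw from the prior.
    """
    rng = np.random.default_rng() if rng is None else rng
    cases = np.asarray(case_count, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(cases < 0) or np.any(cases > total):
        raise ValueError("need 0 <= case_count <= total")
    a, b = prior
    return rng.beta(a + cases, b + (total - cases))


@dataclass
class LogisticUpdateResult:
    theta: np.ndarray
    beta: np.ndarray
    accepted_theta: np.ndarray
    accepted_beta: np.ndarray


def _bern_loglik_eta(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Per-subject Bernoulli log-lik with logit eta, numerically stable."""
    return y * eta - np.logaddexp(0.0, eta)


def update_theta_beta_logistic(z: np.ndarray, y: np.ndarray, W: np.ndarray,
                               theta: np.ndarray, beta: np.ndarray,
                               rng: np.random.Generator,
                               theta_scale=0.3, beta_scale=0.1,
                               prior_sd: float = 10.0) -> LogisticUpdateResult:
    """Metropolis updates of cluster log-odds and confounder coefficients.

    Each theta_k gets an independent Gaussian random-walk proposal (only its
    own cluster's subjects enter the ratio, so all K proposals are evaluated
    in one vectorised pass); each beta_q gets a scalar random-walk against the
    full-data likelihood. Priors are independent Normal(0, prior_sd^2).
    Zero proposal scales leave the corresponding parameters unchanged.
    """
    K = theta.shape[0]
    Q = beta.shape[0]
    theta = theta.copy()
    beta = beta.copy()
    y = np.asarray(y, dtype=float)
    offset = W @ beta if Q else np.zeros_like(y)

    theta_scale = np.broadcast_to(np.asarray(theta_scale, float), (K,))
    prop = theta + theta_scale * rng.standard_normal(K)
    eta_cur = theta[z] + offset
    eta_prop = prop[z] + offset
    d = _bern_loglik_eta(y, eta_prop) - _bern_loglik_eta(y, eta_cur)
    delta = np.bincount(z, weights=d, minlength=K)
    delta += (theta ** 2 - prop ** 2) / (2.0 * prior_sd ** 2)
    acc_t = np.log(rng.random(K)) < delta
    acc_t = np.where(theta_scale == 0.0, True, acc_t)
    moved = acc_t & (theta_scale > 0.0)
    theta[moved] = prop[moved]

    acc_b = np.zeros(Q, dtype=bool)
    if Q:
        beta_scale = np.broadcast_to(np.asarray(beta_scale, float), (Q,))
        eta = theta[z] + W @ beta
        cur_ll = _bern_loglik_eta(y, eta).sum()
        for q in range(Q):
            if beta_scale[q] == 0.0:
                acc_b[q] = True
                continue
            bq = beta[q] + beta_scale[q] * rng.standard_normal()
            eta_new = eta + (bq - beta[q]) * W[:, q]
            new_ll = _bern_loglik_eta(y, eta_new).sum()
            delta = (new_ll - cur_ll
                     + (beta[q] ** 2 - bq ** 2) / (2.0 * prior_sd ** 2))
            if np.log(rng.random()) < delta:
                beta[q] = bq
                eta = eta_new
                cur_ll = new_ll
                acc_b[q] = True
    return LogisticUpdateResult(theta, beta, acc_t, acc_b)
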