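"""Blocked-Gibbs sampler for the joint profile-clustering / disease model.

The mixture over covariate profiles is a Dirichlet-process mixture realised by
truncated stick-breaking (Ishwaran-James blocked Gibbs): K mixture slots with
weights w_k = V_k * prod_{j<k} (1 - V_j), V_k ~ Beta(1, alpha) a priori and
V_K = 1 so the weights sum to one. The number of *occupied* clusters is free
to vary from iteration to iteration; the truncation level only needs to be
large enough that the stick tail is negligible (a warning is logged when the
mass remaining at the last slot exceeds a tolerance).

One sweep updates, in order: allocations z | everything, stick weights and
the concentration alpha, per-cluster category probabilities / ordinal
cutpoints, per-cluster disease parameters (and confounder coefficients in
logistic mode), and finally the missing covariate entries, which are redrawn
from the allocated cluster's category distribution so that imputation is part
of the joint posterior simulation.

Everything recorded in the trace is label-invariant (per-subject risks,
pairwise co-clustering counts, completed covariate draws), so label switching
needs no correction downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .assignment import ordinal_probs, sample_phi_posterior, update_thresholds
from .data import NOMINAL, ORDINAL, ProfileDataset
from .disease import LOGISTIC, PLAIN, sample_theta_plain, update_theta_beta_logistic

logger = logging.getLogger(__name__)

_ADAPT_TARGET = 0.44  # scalar random-walk acceptance target


@dataclass
class McmcConfig:
    """Sampler settings.

    Defaults (30,000 iterations, 10,000 burn-in, thin 10, truncation 50) are
    sized for a study of a few hundred to a few thousand subjects with ~10
    covariates on a single CPU; tests and small experiments pass smaller
    values explicitly.
    """

    n_iter: int = 30_000
    burn_in: int = 10_000
    thin: int = 10
    truncation: int = 50
    mode: str = PLAIN
    # priors
    dirichlet_conc: float = 1.0
    theta_prior: tuple = (1.0, 1.0)      # Beta, plain mode
    theta_sd: float = 10.0               # Normal prior sd, logistic mode
    beta_sd: float = 10.0
    alpha_shape: float = 2.0
    alpha_rate: float = 1.0
    # proposal scales (adapted during burn-in unless adapt=False)
    threshold_scale: float = 0.3
    theta_scale: float = 0.3
    beta_scale: float = 0.1
    alpha_scale: float = 0.5
    adapt: bool = True
    tail_tol: float = 1e-4
    store_imputed: bool = True

    def __post_init__(self) -> None:
        if self.mode not in (PLAIN, LOGISTIC):
            raise ValueError(f"mode must be 'plain' or 'logistic', got {self.mode!r}")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1 or self.truncation < 1:
            raise ValueError("thin and truncation must be >= 1")


@dataclass
class ClusterState:
    """One state of the Markov chain (all K truncation slots instantiated)."""

    z: np.ndarray                 # (n,) allocations in 0..K-1
    V: np.ndarray                 # (K,) stick fractions, V[K-1] == 1
    weights: np.ndarray           # (K,) mixing weights, sum to 1
    alpha: float                  # DP concentration
    probs: list                   # per covariate: (K, M_p) category probabilities
    thresholds: list              # per covariate: (K, M_p - 1) cutpoints or None
    theta: np.ndarray             # (K,) risk (plain) or baseline log-odds (logistic)
    beta: np.ndarray              # (Q,) confounder coefficients
    X_imp: np.ndarray             # (n, P) completed covariates

    @property
    def K(self) -> int:
        return self.weights.shape[0]

    @property
    def K_occupied(self) -> int:
        return int(np.unique(self.z).size)

    def subject_risk(self, mode: str) -> np.ndarray:
        """Per-subject risk on the probability scale (confounders at 0)."""
        t = self.theta[self.z]
        return t if mode == PLAIN else expit(t)


@dataclass
class PosteriorTrace:
    """Retained MCMC output, entirely label-invariant."""

    risks: np.ndarray             # (T, n) per-subject risk, probability scale
    coclust: np.ndarray           # (n, n) co-clustering counts over retained iters
    n_retained: int
    K_occupied: np.ndarray        # (T,)
    alpha: np.ndarray             # (T,)
    loglik: np.ndarray            # (T,) data log-likelihood at the state
    beta: np.ndarray              # (T, Q) confounder coefficients (logistic)
    X_imp_draws: np.ndarray | None  # (T, n, P) int8, completed covariates
    acceptance: dict
    config: McmcConfig
    max_tail_weight: float = 0.0

    @property
    def n(self) -> int:
        return self.risks.shape[1]

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            d / "arrays.npz", risks=self.risks, coclust=self.coclust,
            K_occupied=self.K_occupied, alpha=self.alpha, loglik=self.loglik,
            beta=self.beta,
            **({"X_imp_draws": self.X_imp_draws}
               if self.X_imp_draws is not None else {}))
        meta = {
            "format_version": 1,
            "n_retained": self.n_retained,
            "acceptance": {k: float(v) for k, v in self.acceptance.items()},
            "max_tail_weight": float(self.max_tail_weight),
            "config": asdict(self.config),
        }
        (d / "metadata.json").write_text(json.dumps(meta, indent=2))
        import pandas as pd
        pd.DataFrame({"K_occupied": self.K_occupied, "alpha": self.alpha,
                      "loglik": self.loglik}).to_csv(d / "scalars.csv", index=False)

    @classmethod
    def load(cls, directory) -> "PosteriorTrace":
        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        arr = np.load(d / "arrays.npz")
        cfg = meta["config"]
        cfg["theta_prior"] = tuple(cfg["theta_prior"])
        return cls(risks=arr["risks"], coclust=arr["coclust"],
                   n_retained=meta["n_retained"], K_occupied=arr["K_occupied"],
                   alpha=arr["alpha"], loglik=arr["loglik"], beta=arr["beta"],
                   X_imp_draws=arr["X_imp_draws"] if "X_imp_draws" in arr else None,
                   acceptance=meta["acceptance"], config=McmcConfig(**cfg),
                   max_tail_weight=meta["max_tail_weight"])


# ---------------------------------------------------------------------------
# state initialisation and the single Gibbs sweep


def _stick_weights(V: np.ndarray) -> np.ndarray:
    one_minus = np.concatenate([[1.0], np.cumprod(1.0 - V[:-1])])
    return V * one_minus


def init_state(data: ProfileDataset, config: McmcConfig,
               rng: np.random.Generator) -> ClusterState:
    """Draw an initial state from the prior (also the exact prior sampler
    used by joint-distribution validation)."""
    n, P = data.X.shape
    K = config.truncation
    alpha = rng.gamma(config.alpha_shape, 1.0 / config.alpha_rate)
    V = np.empty(K)
    V[:-1] = rng.beta(1.0, alpha, size=K - 1)
    V[-1] = 1.0
    weights = _stick_weights(V)
    z = rng.choice(K, size=n, p=weights)
    probs: list = []
    thresholds: list = []
    for spec in data.specs:
        M = spec.n_categories
        ph = sample_phi_posterior(np.zeros((K, M)),
                                  np.full(M, config.dirichlet_conc), rng)
        if spec.kind == ORDINAL:
            from .assignment import probs_to_thresholds
            thr = probs_to_thresholds(ph)
            thresholds.append(np.atleast_2d(thr))
            probs.append(ordinal_probs(thr, M))
        else:
            thresholds.append(None)
            probs.append(ph)
    if config.mode == PLAIN:
        if data.n_confounders:
            raise ValueError("plain mode admits no confounders; use mode='logistic'")
        theta = rng.beta(*config.theta_prior, size=K)
    else:
        theta = rng.normal(0.0, config.theta_sd, size=K)
    beta = rng.normal(0.0, config.beta_sd, size=data.n_confounders)
    X_imp = data.X.copy()
    for p in range(P):
        rows = np.where(data.missing_mask[:, p])[0]
        if rows.size:
            X_imp[rows, p] = _categorical_rows(probs[p][z[rows]], rng)
    return ClusterState(z, V, weights, float(alpha), probs, thresholds,
                        theta, beta, X_imp)


def _categorical_rows(P_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a row-stochastic matrix."""
    u = rng.random((P_rows.shape[0], 1))
    return (u < np.cumsum(P_rows, axis=1)).argmax(axis=1)


@dataclass
class _AdaptState:
    """Per-parameter proposal scales, Robbins-Monro adapted in burn-in."""

    thr_log: list            # per covariate (K, M-1) log-scales or None
    theta_log: np.ndarray
    beta_log: np.ndarray
    alpha_log: float
    t: int = 0
    step_size: float = 0.0

    @classmethod
    def for_data(cls, data: ProfileDataset, config: McmcConfig) -> "_AdaptState":
        K = config.truncation
        thr = [np.full((K, s.n_categories - 1), np.log(config.threshold_scale))
               if s.kind == ORDINAL else None for s in data.specs]
        return cls(thr, np.full(K, np.log(config.theta_scale)),
                   np.full(data.n_confounders, np.log(config.beta_scale)),
                   float(np.log(config.alpha_scale)))

    def step(self) -> float:
        self.t += 1
        return (self.t + 10.0) ** -0.6


def allocation_logits(state: ClusterState, data: ProfileDataset,
                      config: McmcConfig) -> np.ndarray:
    """Unnormalised log allocation probabilities, shape (n, K): log weight +
    profile log-likelihood (imputed covariates) + outcome log-likelihood."""
    n, P = data.X.shape
    yf = data.y.astype(float)
    with np.errstate(divide="ignore"):
        logits = np.log(state.weights)[None, :].repeat(n, axis=0)
        for p in range(P):
            lp = np.log(state.probs[p])          # (K, M)
            logits += lp[:, state.X_imp[:, p]].T
        if config.mode == PLAIN:
            lt = np.log(state.theta)
            lt1 = np.log1p(-state.theta)
            logits += (yf[:, None] * lt[None, :]
                       + (1.0 - yf)[:, None] * lt1[None, :])
        else:
            eta = state.theta[None, :]
            if state.beta.size:
                eta = eta + (data.W @ state.beta)[:, None]
            logits += yf[:, None] * eta - np.logaddexp(0.0, eta)
    return logits


def update_allocations(state: ClusterState, data: ProfileDataset,
                       config: McmcConfig, rng: np.random.Generator) -> None:
    """Resample every allocation z_i from its categorical full conditional
    (Gumbel-max draw, one vectorised pass)."""
    logits = allocation_logits(state, data, config)
    gumbel = -np.log(-np.log(rng.random(logits.shape)))
    state.z = (logits + gumbel).argmax(axis=1)


def update_weights_alpha(state: ClusterState, config: McmcConfig,
                         rng: np.random.Generator,
                         adapt: "_AdaptState | None" = None,
                         adapting: bool = False) -> bool:
    """Redraw stick fractions from their Beta full conditionals given the
    allocation counts, then update the concentration alpha by a random-walk
    Metropolis step on log alpha under its Gamma prior. Returns the alpha
    acceptance flag."""
    K = state.K
    counts = np.bincount(state.z, minlength=K).astype(float)
    tail_counts = counts[::-1].cumsum()[::-1] - counts
    V = np.empty(K)
    V[:-1] = rng.beta(1.0 + counts[:-1], state.alpha + tail_counts[:-1])
    V[-1] = 1.0
    state.V = V
    state.weights = _stick_weights(V)

    S = np.log1p(-np.minimum(V[:-1], 1.0 - 1e-12)).sum()
    a0, b0 = config.alpha_shape, config.alpha_rate

    def logpost(a: float) -> float:
        return ((a0 - 1.0) * np.log(a) - b0 * a
                + (K - 1) * np.log(a) + (a - 1.0) * S)

    la = np.log(state.alpha)
    scale = np.exp(adapt.alpha_log) if adapt is not None else config.alpha_scale
    la_prop = la + scale * rng.standard_normal()
    ratio = logpost(np.exp(la_prop)) + la_prop - logpost(state.alpha) - la
    accepted = bool(np.log(rng.random()) < ratio)
    if accepted:
        state.alpha = float(np.exp(la_prop))
    if adapt is not None and adapting:
        adapt.alpha_log += adapt.step_size * (float(accepted) - _ADAPT_TARGET)
    return accepted


def update_cluster_params(state: ClusterState, data: ProfileDataset,
                          config: McmcConfig, rng: np.random.Generator,
                          adapt: "_AdaptState | None" = None,
                          adapting: bool = False) -> float:
    """Per-cluster category parameters: conjugate Dirichlet draws for nominal
    covariates, batched Metropolis cutpoint updates for ordinal ones (empty
    clusters thereby sample their prior). Returns the mean cutpoint
    acceptance rate (1.0 if no ordinal covariates)."""
    K = state.K
    acc_num = acc_den = 0.0
    for p, spec in enumerate(data.specs):
        M = spec.n_categories
        cat_counts = np.bincount(state.z * M + state.X_imp[:, p],
                                 minlength=K * M).reshape(K, M).astype(float)
        if spec.kind == NOMINAL:
            state.probs[p] = sample_phi_posterior(
                cat_counts, np.full(M, config.dirichlet_conc), rng)
        else:
            scale = (np.exp(adapt.thr_log[p]) if adapt is not None
                     else config.threshold_scale)
            thr, acc = update_thresholds(state.thresholds[p], cat_counts,
                                         scale, rng)
            state.thresholds[p] = thr
            state.probs[p] = ordinal_probs(thr, M)
            acc_num += acc.sum()
            acc_den += acc.size
            if adapt is not None and adapting:
                adapt.thr_log[p] += adapt.step_size * (acc - _ADAPT_TARGET)
    return acc_num / acc_den if acc_den else 1.0


def update_disease_params(state: ClusterState, data: ProfileDataset,
                          config: McmcConfig, rng: np.random.Generator,
                          adapt: "_AdaptState | None" = None,
                          adapting: bool = False) -> tuple:
    """Disease submodel update: conjugate Beta draws in plain mode, Metropolis
    on cluster log-odds and confounder coefficients in logistic mode (empty
    clusters redrawn from the prior). Returns (theta_acc, beta_acc) rates."""
    K = state.K
    yf = data.y.astype(float)
    counts = np.bincount(state.z, minlength=K).astype(float)
    if config.mode == PLAIN:
        cases = np.bincount(state.z, weights=yf, minlength=K)
        state.theta = sample_theta_plain(cases, counts, config.theta_prior, rng)
        return 1.0, 1.0
    scale_t = np.exp(adapt.theta_log) if adapt is not None else config.theta_scale
    scale_b = np.exp(adapt.beta_log) if adapt is not None else config.beta_scale
    res = update_theta_beta_logistic(state.z, data.y, data.W, state.theta,
                                     state.beta, rng, scale_t, scale_b,
                                     config.theta_sd)
    state.theta, state.beta = res.theta, res.beta
    empty = counts == 0
    if empty.any():
        state.theta[empty] = rng.normal(0.0, config.theta_sd, int(empty.sum()))
    if adapt is not None and adapting:
        adapt.theta_log += adapt.step_size * (res.accepted_theta - _ADAPT_TARGET)
        if res.accepted_beta.size:
            adapt.beta_log += adapt.step_size * (res.accepted_beta - _ADAPT_TARGET)
    return (float(res.accepted_theta.mean()),
            float(res.accepted_beta.mean()) if res.accepted_beta.size else 1.0)


def impute_missing(state: ClusterState, data: ProfileDataset,
                   rng: np.random.Generator) -> None:
    """Redraw every missing covariate entry from the allocated cluster's
    category distribution; observed entries are untouched."""
    P = data.X.shape[1]
    miss_rows = getattr(data, "_miss_rows", None)
    for p in range(P):
        rows = (miss_rows[p] if miss_rows is not None
                else np.where(data.missing_mask[:, p])[0])
        if rows.size:
            state.X_imp[rows, p] = _categorical_rows(
                state.probs[p][state.z[rows]], rng)


def sweep(state: ClusterState, data: ProfileDataset, config: McmcConfig,
          rng: np.random.Generator, adapt: "_AdaptState | None" = None,
          adapting: bool = False, accum: dict | None = None) -> ClusterState:
    """One full Gibbs sweep (allocations, weights/alpha, profile parameters,
    disease parameters, imputation), mutating and returning ``state``."""
    update_allocations(state, data, config, rng)
    acc_alpha = update_weights_alpha(state, config, rng, adapt, adapting)
    acc_thr = update_cluster_params(state, data, config, rng, adapt, adapting)
    acc_theta, acc_beta = update_disease_params(state, data, config, rng,
                                                adapt, adapting)
    impute_missing(state, data, rng)
    if accum is not None:
        accum["alpha"] += float(acc_alpha)
        accum["theta"] += acc_theta
        accum["beta"] += acc_beta
        if any(s.kind == ORDINAL for s in data.specs):
            accum["thresholds"] += acc_thr
            accum["_thr_n"] += 1
        accum["_n"] += 1
    return state


def data_loglik(state: ClusterState, data: ProfileDataset,
                config: McmcConfig) -> float:
    """Log-likelihood of (completed) covariates and outcome at the state."""
    n, P = data.X.shape
    ll = 0.0
    for p in range(P):
        ll += float(np.log(state.probs[p][state.z, state.X_imp[:, p]]).sum())
    r = state.subject_risk(config.mode)
    yf = data.y.astype(float)
    ll += float((yf * np.log(r) + (1 - yf) * np.log1p(-r)).sum())
    return ll


def sample_data_from_state(state: ClusterState, data: ProfileDataset,
                           config: McmcConfig,
                           rng: np.random.Generator) -> ProfileDataset:
    """Regenerate (X, y) from the current parameters and allocations, in place.

    Used by joint-distribution (successive-conditional) validation: covariates
    are drawn from the allocated cluster's category distributions and the
    outcome from the allocated cluster's risk. The dataset is mutated without
    re-validation (an all-case or all-control draw is a legal state of the
    generative model even though it is rejected at load time), so the data
    must have no missing entries.
    """
    if data.missing_mask.any():
        raise ValueError("in-place data regeneration assumes complete data")
    n, P = data.X.shape
    for p in range(P):
        data.X[:, p] = _categorical_rows(state.probs[p][state.z], rng)
    r = state.subject_risk(config.mode)
    data.y[:] = (rng.random(n) < r).astype(np.int64)
    state.X_imp = data.X.copy()
    return data


def run_mcmc(data: ProfileDataset, config: McmcConfig | None = None,
             seed: int | np.random.Generator = 0,
             callback=None) -> PosteriorTrace:
    """Run the full sampler and return the retained, label-invariant trace.

    Deterministic given ``seed``. ``callback(iteration, state)`` is invoked
    after every sweep when provided (progress logging, custom recording).
    """
    config = McmcConfig() if config is None else config
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n, P = data.X.shape
    # cache missing-row indices on the dataset for the imputation step
    data._miss_rows = [np.where(data.missing_mask[:, p])[0] for p in range(P)]

    state = init_state(data, config, rng)
    adapt = _AdaptState.for_data(data, config) if config.adapt else None
    T = (config.n_iter - config.burn_in) // config.thin
    if T < 1:
        raise ValueError("no retained iterations: check n_iter/burn_in/thin")

    risks = np.empty((T, n))
    K_occ = np.empty(T, dtype=np.int64)
    alphas = np.empty(T)
    logliks = np.empty(T)
    betas = np.empty((T, data.n_confounders))
    coclust = np.zeros((n, n))
    X_draws = (np.empty((T, n, P), dtype=np.int8)
               if config.store_imputed else None)
    accum = {"alpha": 0.0, "theta": 0.0, "beta": 0.0, "thresholds": 0.0,
             "_n": 0, "_thr_n": 0}
    max_tail = 0.0
    t = 0
    for it in range(1, config.n_iter + 1):
        adapting = config.adapt and it <= config.burn_in
        if adapt is not None:
            adapt.step_size = adapt.step()
        sweep(state, data, config, rng, adapt, adapting, accum)
        if it > config.burn_in:
            max_tail = max(max_tail, float(state.weights[-1]))
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            risks[t] = state.subject_risk(config.mode)
            K_occ[t] = state.K_occupied
            alphas[t] = state.alpha
            logliks[t] = data_loglik(state, data, config)
            betas[t] = state.beta
            coclust += state.z[:, None] == state.z[None, :]
            if X_draws is not None:
                X_draws[t] = state.X_imp
            t += 1
        if callback is not None:
            callback(it, state)
    del data._miss_rows
    if max_tail > config.tail_tol:
        logger.warning(
            "stick tail mass reached %.3g (> %.1g): consider raising the "
            "truncation level (%d)", max_tail, config.tail_tol, config.truncation)
    nrec = max(accum["_n"], 1)
    acceptance = {
        "alpha": accum["alpha"] / nrec,
        "theta": accum["theta"] / nrec,
        "beta": accum["beta"] / nrec,
        "thresholds": (accum["thresholds"] / accum["_thr_n"]
                       if accum["_thr_n"] else 1.0),
    }
    return PosteriorTrace(risks=risks, coclust=coclust, n_retained=T,
                          K_occupied=K_occ, alpha=alphas, loglik=logliks,
                          beta=betas,
                          X_imp_draws=X_draws, acceptance=acceptance,
                          config=config, max_tail_weight=max_tail)
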