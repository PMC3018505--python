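"""Synthetic case-control generators with planted cluster structure.

The main generator draws each subject's cluster from fixed mixing weights,
its covariates from cluster-specific category probabilities, and its outcome
from the cluster's risk (optionally through a logistic link with confounder
effects) — exactly the generative structure the profile-regression model
assumes — then applies missing-completely-at-random masking per covariate.
Ground-truth labels and parameters are returned for recovery tests.

Shipped presets (YAML under ``profilereg/presets``):

``paper_shape``
    A study-shaped scenario: 829 subjects, nine covariates (three binary,
    four 3-level, two 4-level), three clusters of expected sizes 96/112/621
    with risks 0.15/0.12/0.09, and 30% missingness on one ordinal covariate
    (overall outcome prevalence ~10%).
``separable``
    900 subjects, three well-separated clusters with risks 0.25/0.10/0.05 —
    the end-to-end recovery scenario.
``null``
    One cluster, no risk structure.
``xor_pair``
    A pure two-factor interaction with null marginals, for MDR recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy.special import expit

from .data import MISSING, NOMINAL, CovariateSpec, ProfileDataset

__all__ = ["SyntheticSpec", "make_synthetic", "make_mdr_synthetic",
           "load_preset", "generate_preset", "preset_names"]


@dataclass
class SyntheticSpec:
    """Planted-structure description for :func:`make_synthetic`.

    ``phi`` holds one array of shape (K, M_p) per covariate: cluster-specific
    category probabilities (ordinal covariates are specified on the
    probability scale too; the model converts to thresholds internally).
    ``theta`` is the per-cluster risk in (0, 1); when ``beta`` is given the
    outcome is Bernoulli(expit(logit(theta_k) + beta . w)) with standard-normal
    confounders.
    """

    n: int
    cluster_weights: np.ndarray
    phi: list
    theta: np.ndarray
    specs: list
    missing_rate: np.ndarray | None = None   # per covariate, MCAR
    beta: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.cluster_weights = np.asarray(self.cluster_weights, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.phi = [np.asarray(ph, dtype=float) for ph in self.phi]
        if abs(self.cluster_weights.sum() - 1.0) > 1e-8:
            raise ValueError("cluster weights must sum to 1")
        if np.any((self.theta <= 0) | (self.theta >= 1)):
            raise ValueError("cluster risks must lie in (0, 1)")
        K = self.cluster_weights.size
        for p, (ph, spec) in enumerate(zip(self.phi, self.specs)):
            if ph.shape != (K, spec.n_categories):
                raise ValueError(f"phi[{p}] must have shape "
                                 f"({K}, {spec.n_categories}), got {ph.shape}")
            if np.any(np.abs(ph.sum(axis=1) - 1.0) > 1e-8):
                raise ValueError(f"phi[{p}] rows must sum to 1")
        if self.missing_rate is not None:
            self.missing_rate = np.asarray(self.missing_rate, dtype=float)
            if self.missing_rate.shape != (len(self.specs),):
                raise ValueError("missing_rate must have one entry per covariate")

    @property
    def n_clusters(self) -> int:
        return self.cluster_weights.size


def make_synthetic(spec: SyntheticSpec, seed=None):
    """Generate a dataset from a planted-cluster specification.

    Returns ``(dataset, labels, truth)`` where ``truth`` records the planted
    weights, category probabilities and risks.
    """
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n, P, K = spec.n, len(spec.specs), spec.n_clusters
    labels = rng.choice(K, size=n, p=spec.cluster_weights)
    X = np.empty((n, P), dtype=np.int64)
    for p in range(P):
        probs = spec.phi[p][labels]
        u = rng.random((n, 1))
        X[:, p] = (u < np.cumsum(probs, axis=1)).argmax(axis=1)
    if spec.beta is not None and np.size(spec.beta):
        beta = np.asarray(spec.beta, dtype=float)
        W = rng.standard_normal((n, beta.size))
        eta = np.log(spec.theta[labels] / (1 - spec.theta[labels])) + W @ beta
        risk = expit(eta)
    else:
        W = np.zeros((n, 0))
        risk = spec.theta[labels]
    y = (rng.random(n) < risk).astype(np.int64)
    if not (y.any() and (1 - y).any()):
        raise ValueError("degenerate outcome draw: all cases or all controls; "
                         "increase n or adjust risks")
    if spec.missing_rate is not None:
        mask = rng.random((n, P)) < spec.missing_rate[None, :]
        X[mask] = MISSING
    data = ProfileDataset(X, y, W, list(spec.specs))
    truth = {"weights": spec.cluster_weights, "phi": spec.phi,
             "theta": spec.theta, "beta": spec.beta}
    return data, labels, truth


def make_mdr_synthetic(n: int, planted_pair_effect: float, seed=0,
                       n_factors: int = 6, base_risk: float = 0.15,
                       pair: tuple = (0, 1)):
    """Binary-factor dataset whose outcome depends only on one interaction.

    Factors are iid fair coins; the outcome risk is ``base_risk`` when the
    designated pair's XOR is 0 and ``base_risk + planted_pair_effect`` when
    it is 1. Because the XOR of two fair coins is independent of each coin,
    every marginal association is null — only the joint pair is informative.
    For the interaction to be visible at the default cell-labelling threshold
    (cases > controls), the elevated risk must exceed 0.5, so a strong
    scenario needs ``base_risk + planted_pair_effect > 0.5``.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    if not 0 <= base_risk + planted_pair_effect < 1:
        raise ValueError("base_risk + effect must lie in [0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    X = rng.integers(0, 2, size=(n, n_factors))
    xor = X[:, pair[0]] ^ X[:, pair[1]]
    risk = base_risk + planted_pair_effect * xor
    y = (rng.random(n) < risk).astype(np.int64)
    if not (y.any() and (1 - y).any()):
        raise ValueError("degenerate outcome draw; increase n")
    specs = [CovariateSpec(f"f{i}", NOMINAL, 2) for i in range(n_factors)]
    return ProfileDataset(X, y, np.zeros((n, 0)), specs)


# ---------------------------------------------------------------------------
# presets


def _read_preset(name: str) -> dict:
    ref = resources.files("profilereg").joinpath(f"presets/{name}.yaml")
    try:
        return yaml.safe_load(ref.read_text())
    except FileNotFoundError:
        raise ValueError(f"unknown preset {name!r}; "
                         f"available: {preset_names()}") from None


def generate_preset(name: str, seed=0, n: int | None = None):
    """Generate a dataset from any shipped preset.

    Returns ``(dataset, labels, truth)``; ``labels`` is None for the MDR
    interaction scenario (it has no cluster structure). ``n`` overrides the
    preset's sample size.
    """
    raw = _read_preset(name)
    if raw.get("kind") == "mdr_xor":
        data = make_mdr_synthetic(n or int(raw["n"]), float(raw["effect"]),
                                  seed=seed, n_factors=int(raw["n_factors"]),
                                  base_risk=float(raw["base_risk"]),
                                  pair=tuple(raw["pair"]))
        truth = {"pair": tuple(raw["pair"]), "effect": float(raw["effect"]),
                 "base_risk": float(raw["base_risk"])}
        return data, None, truth
    spec = load_preset(name)
    if n is not None:
        spec.n = n
    return make_synthetic(spec, seed=seed)


def preset_names() -> list:
    files = resources.files("profilereg").joinpath("presets")
    return sorted(p.name.removesuffix(".yaml") for p in files.iterdir()
                  if p.name.endswith(".yaml"))


def load_preset(name: str) -> SyntheticSpec:
    """Load a shipped cluster-structure scenario by name (see module docstring).

    The ``xor_pair`` preset describes an interaction-only scenario handled by
    :func:`make_mdr_synthetic`; use :func:`generate_preset` for a uniform
    interface over all presets.
    """
    raw = _read_preset(name)
    if raw.get("kind") == "mdr_xor":
        raise ValueError(f"preset {name!r} is an MDR interaction scenario; "
                         "use generate_preset()")
    specs = [CovariateSpec(c["name"], c["kind"], int(c["n_categories"]))
             for c in raw["covariates"]]
    K = len(raw["cluster_weights"])
    phi = []
    for p, c in enumerate(raw["covariates"]):
        if "phi" in c:
            phi.append(np.asarray(c["phi"], dtype=float))
        else:
            # concentration pattern: each cluster prefers an anchor category
            M = specs[p].n_categories
            anchors = c.get("anchors", [round(k * (M - 1) / max(K - 1, 1))
                                        for k in range(K)])
            strength = float(c.get("anchor_mass", raw.get("anchor_mass", 0.7)))
            mat = np.full((K, M), (1.0 - strength) / (M - 1))
            for k, a in enumerate(anchors):
                mat[k, int(a)] = strength
            phi.append(mat)
    return SyntheticSpec(
        n=int(raw["n"]),
        cluster_weights=np.asarray(raw["cluster_weights"], dtype=float),
        phi=phi,
        theta=np.asarray(raw["theta"], dtype=float),
        specs=specs,
        missing_rate=(np.asarray(raw["missing_rate"], dtype=float)
                      if "missing_rate" in raw else None),
        seed=raw.get("seed"),
    )
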