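"""scikit-learn style estimators wrapping the profile-regression sampler and
the MDR scan.

``ProfileRegression`` behaves like a clustering estimator (``fit`` /
``fit_predict`` producing ``labels_``) that additionally yields per-subject
risk estimates and group-level posterior summaries. ``MDRScan`` behaves like
a classifier built on the winning factor combination. Both compose with
sklearn model-selection utilities through ``get_params`` / ``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .data import CovariateSpec, NOMINAL, ProfileDataset
from .mdr import mdr_scan, predict_cells
from .postprocess import (best_partition, build_similarity,
                          profile_deviation_intervals, summarize_groups)
from .sampler import McmcConfig, run_mcmc


def _coerce_dataset(X, y=None, specs=None, W=None) -> ProfileDataset:
    if isinstance(X, ProfileDataset):
        return X
    X = np.asarray(X)
    if y is None:
        raise ValueError("y (binary outcome) is required")
    if specs is None:
        # treat unlabelled integer columns as nominal with observed range
        specs = [CovariateSpec(f"x{p}", NOMINAL, int(X[:, p].max() + 1))
                 for p in range(X.shape[1])]
    return ProfileDataset(X, np.asarray(y), W, list(specs))


class ProfileRegression(ClusterMixin, BaseEstimator):
    """Bayesian profile regression: outcome-guided profile clustering.

    A Dirichlet-process mixture over integer-coded covariate profiles is fit
    jointly with a per-cluster disease parameter by MCMC; the posterior
    co-clustering matrix is condensed into a deterministic best partition,
    and each group is summarised by its posterior risk distribution,
    exceedance probability against the sample-average risk, and odds ratio
    against the lowest-risk reference group.

    Parameters mirror :class:`~profilereg.sampler.McmcConfig`; ``n_groups``
    is the candidate range for the representative partition (int, iterable,
    or None for an automatic range).

    Attributes (after ``fit``)
    --------------------------
    trace_ : PosteriorTrace
    similarity_ : (n, n) posterior co-clustering probabilities
    labels_ : best-partition group ids (0-based, decreasing size)
    n_groups_ : number of groups in the best partition
    risk_ : posterior-mean per-subject risk
    group_summary_ : DataFrame of per-group risk/OR summaries
    profile_deviations_ : DataFrame of per-group covariate deviations
    """

    def __init__(self, *, n_iter=30_000, burn_in=10_000, thin=10,
                 truncation=50, mode="plain", n_groups=None,
                 reference="lowest", dirichlet_conc=1.0,
                 theta_prior=(1.0, 1.0), theta_sd=10.0, beta_sd=10.0,
                 alpha_shape=2.0, alpha_rate=1.0, store_imputed=True,
                 random_state=None):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.truncation = truncation
        self.mode = mode
        self.n_groups = n_groups
        self.reference = reference
        self.dirichlet_conc = dirichlet_conc
        self.theta_prior = theta_prior
        self.theta_sd = theta_sd
        self.beta_sd = beta_sd
        self.alpha_shape = alpha_shape
        self.alpha_rate = alpha_rate
        self.store_imputed = store_imputed
        self.random_state = random_state

    def _config(self) -> McmcConfig:
        return McmcConfig(
            n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin,
            truncation=self.truncation, mode=self.mode,
            dirichlet_conc=self.dirichlet_conc,
            theta_prior=tuple(self.theta_prior), theta_sd=self.theta_sd,
            beta_sd=self.beta_sd, alpha_shape=self.alpha_shape,
            alpha_rate=self.alpha_rate, store_imputed=self.store_imputed)

    def fit(self, X, y=None, *, specs=None, W=None):
        """Run the sampler and derive the representative partition.

        ``X`` may be a :class:`ProfileDataset` (then ``y`` is ignored) or an
        integer-coded matrix with ``y`` the 0/1 outcome and optional
        ``specs`` / ``W``.
        """
        data = _coerce_dataset(X, y, specs, W)
        seed = (self.random_state if self.random_state is not None else 0)
        trace = run_mcmc(data, self._config(), seed=seed)
        self.dataset_ = data
        self.trace_ = trace
        self.similarity_ = build_similarity(trace)
        G_range = self.n_groups
        if isinstance(G_range, (int, np.integer)):
            G_range = [int(G_range)]
        part = best_partition(self.similarity_, G_range)
        self.labels_ = part.labels
        self.n_groups_ = part.n_groups
        self.partition_ = part
        self.risk_ = trace.risks.mean(axis=0)
        self.group_summary_ = summarize_groups(trace, part.labels,
                                               self.reference)
        if trace.X_imp_draws is not None:
            self.profile_deviations_ = profile_deviation_intervals(
                trace, part.labels, data)
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, y, **kwargs).labels_

    def predict_proba(self, X=None):
        """Posterior-mean risk of the *training* subjects (transductive)."""
        check_is_fitted(self, "risk_")
        if X is not None:
            raise ValueError("ProfileRegression is transductive: risks are "
                             "defined for the fitted subjects only")
        return self.risk_

    def score(self, X=None, y=None):
        """Negative squared-residual fit score of the training fit."""
        check_is_fitted(self, "risk_")
        from .postprocess import fit_residual_score
        return -fit_residual_score(self.risk_, self.dataset_.y)


class MDRScan(BaseEstimator):
    """Exhaustive multifactor-dimensionality-reduction scan.

    Fits the full scan over factor subsets of orders ``1..max_order`` and
    exposes the winning combination as a cell-label classifier.

    Attributes (after ``fit``)
    --------------------------
    results_ : DataFrame with one row per order (factors, accuracy,
        cross-validation consistency)
    best_factors_ : winning factor index tuple
    accuracy_, consistency_ : the winner's scores
    """

    def __init__(self, *, max_order=2, threshold=1.0, n_folds=10,
                 max_combinations=200_000, random_state=None):
        self.max_order = max_order
        self.threshold = threshold
        self.n_folds = n_folds
        self.max_combinations = max_combinations
        self.random_state = random_state

    def fit(self, X, y=None):
        data = X if isinstance(X, ProfileDataset) else (np.asarray(X),
                                                        np.asarray(y))
        seed = self.random_state if self.random_state is not None else 0
        res = mdr_scan(data, self.max_order, self.threshold, self.n_folds,
                       seed=seed, max_combinations=self.max_combinations)
        self.result_ = res
        self.results_ = res.table
        self.best_factors_ = res.best_factors
        row = res.table.loc[res.table["factors"] == res.best_factors].iloc[0]
        self.accuracy_ = float(row["accuracy"])
        self.consistency_ = int(row["consistency"])
        return self

    def predict(self, X):
        """0/1 prediction from the winning combination's cell labels."""
        check_is_fitted(self, "result_")
        X = X.X if isinstance(X, ProfileDataset) else np.asarray(X)
        return predict_cells(X, self.best_factors_, self.result_.best_cells)

    def score(self, X, y):
        y = np.asarray(y.y if isinstance(y, ProfileDataset) else y)
        return float((self.predict(X) == y).mean())
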