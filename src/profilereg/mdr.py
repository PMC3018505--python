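"""Multifactor dimensionality reduction (MDR) comparator.

For a chosen set of factors, every observed combination cell is labelled
high- or low-risk according to whether its case:control ratio exceeds a
threshold (default 1). Prediction accuracy is estimated by 10-fold
cross-validation (cells labelled on 90% of the data, the held-out 10%
predicted by the trained labels), and the exhaustive scan over all factor
subsets of each order reports the winning subset's mean prediction accuracy
and its cross-validation consistency — the number of folds (out of 10) in
which that subset was the per-fold winner.

Deterministic conventions (MDR is sensitive to sparse cells): cells absent
from the training data are predicted as the majority class ("low" under
prevalence < 0.5); non-empty cells with zero controls are labelled "high";
ties between factor subsets are broken lexicographically by factor indices.
Folds are stratified by outcome so that low-prevalence samples retain cases
in every fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .data import ProfileDataset

__all__ = ["label_cells", "predict_cells", "stratified_folds",
           "cross_validate", "mdr_scan", "MdrResult"]

HIGH, LOW = "high", "low"


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, ProfileDataset):
        if data.missing_mask.any():
            raise ValueError("MDR requires complete data; subset to complete "
                             "cases first (ProfileDataset.complete_cases)")
        return data.X, data.y
    X, y = data
    return np.asarray(X), np.asarray(y)


def label_cells(data, factors, threshold: float = 1.0) -> dict:
    """Label every observed factor-combination cell high or low risk.

    Returns a dict mapping each observed level combination (tuple) to
    ``"high"`` or ``"low"``: high when cases/controls > threshold, with
    zero-control non-empty cells counted as high.
    """
    X, y = _as_xy(data)
    factors = tuple(factors)
    if not factors:
        raise ValueError("factors must be non-empty")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sub = X[:, factors]
    cells, inv = np.unique(sub, axis=0, return_inverse=True)
    cases = np.bincount(inv, weights=y, minlength=len(cells))
    totals = np.bincount(inv, minlength=len(cells))
    controls = totals - cases
    labels = {}
    for c, ca, co in zip(cells, cases, controls):
        if co == 0:
            lab = HIGH  # non-empty cell with no controls
        else:
            lab = HIGH if ca / co > threshold else LOW
        labels[tuple(int(v) for v in c)] = lab
    return labels


def predict_cells(X: np.ndarray, factors, labels: dict) -> np.ndarray:
    """Predict 0/1 outcomes from trained cell labels (unseen cells -> low)."""
    sub = np.asarray(X)[:, tuple(factors)]
    return np.array([1 if labels.get(tuple(int(v) for v in row)) == HIGH else 0
                     for row in sub], dtype=np.int64)


def stratified_folds(y: np.ndarray, n_folds: int, seed) -> np.ndarray:
    """Deterministic outcome-stratified fold assignment (0..n_folds-1)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    y = np.asarray(y)
    if y.size < n_folds:
        raise ValueError("need at least one subject per fold")
    folds = np.empty(y.size, dtype=np.int64)
    for cls in (0, 1):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def _accuracy(pred: np.ndarray, y: np.ndarray) -> float:
    return float((pred == y).mean())


def cross_validate(data, factors, threshold: float = 1.0, n_folds: int = 10,
                   seed=0, folds: np.ndarray | None = None):
    """Cross-validated prediction accuracy for one factor subset.

    Returns ``(mean_accuracy, per_fold_accuracies)``. A fold without cases is
    retained (it merely yields a trivially easy test fold); stratification
    makes this rare.
    """
    X, y = _as_xy(data)
    if folds is None:
        folds = stratified_folds(y, n_folds, seed)
    accs = np.empty(n_folds)
    for f in range(n_folds):
        test = folds == f
        labels = label_cells((X[~test], y[~test]), factors, threshold)
        accs[f] = _accuracy(predict_cells(X[test], factors, labels), y[test])
    return float(accs.mean()), accs


@dataclass
class MdrResult:
    """Exhaustive-scan output, one row per interaction order."""

    table: pd.DataFrame           # order, factors, accuracy, consistency
    best_cells: dict              # winning subset's full-data cell labels
    best_factors: tuple
    folds: np.ndarray

    @property
    def best_order(self) -> int:
        return len(self.best_factors)


def mdr_scan(data, max_order: int, threshold: float = 1.0, n_folds: int = 10,
             seed=0, max_combinations: int = 200_000,
             factor_names: list | None = None) -> MdrResult:
    """Exhaustive scan over all factor subsets of orders 1..max_order.

    For each order p, every p-subset is scored: the per-fold winner is the
    subset with the highest training-set classification accuracy in that
    fold (ties lexicographic), and the order's reported winner is the subset
    with the highest mean cross-validated prediction accuracy. The winner's
    cross-validation consistency is the number of folds in which it was the
    per-fold winner. The overall ``best_factors`` maximise (accuracy,
    consistency) across orders.
    """
    X, y = _as_xy(data)
    P = X.shape[1]
    if not 1 <= max_order <= P:
        raise ValueError(f"max_order must be in 1..{P}")
    total = sum(comb(P, p) for p in range(1, max_order + 1))
    if total > max_combinations:
        raise ValueError(f"{total} factor subsets exceed the "
                         f"max_combinations guard ({max_combinations})")
    if isinstance(data, ProfileDataset) and factor_names is None:
        factor_names = [s.name for s in data.specs]
    folds = stratified_folds(y, n_folds, seed)

    rows = []
    for order in range(1, max_order + 1):
        subsets = list(combinations(range(P), order))
        mean_acc = np.zeros(len(subsets))
        train_acc = np.zeros((len(subsets), n_folds))
        for s_idx, factors in enumerate(subsets):
            accs = np.empty(n_folds)
            for f in range(n_folds):
                test = folds == f
                labels = label_cells((X[~test], y[~test]), factors, threshold)
                train_acc[s_idx, f] = _accuracy(
                    predict_cells(X[~test], factors, labels), y[~test])
                accs[f] = _accuracy(
                    predict_cells(X[test], factors, labels), y[test])
            mean_acc[s_idx] = accs.mean()
        fold_winner = train_acc.argmax(axis=0)  # argmax is lexicographic-first
        winner = int(mean_acc.argmax())
        consistency = int((fold_winner == winner).sum())
        factors = subsets[winner]
        rows.append({
            "order": order,
            "factors": factors,
            "factor_names": (tuple(factor_names[i] for i in factors)
                             if factor_names else factors),
            "accuracy": float(mean_acc[winner]),
            "consistency": consistency,
            "n_folds": n_folds,
        })
    table = pd.DataFrame(rows)
    best_row = table.sort_values(["accuracy", "consistency", "order"],
                                 ascending=[False, False, True],
                                 kind="stable").iloc[0]
    best_factors = tuple(best_row["factors"])
    best_cells = label_cells((X, y), best_factors, threshold)
    return MdrResult(table=table, best_cells=best_cells,
                     best_factors=best_factors, folds=folds)
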