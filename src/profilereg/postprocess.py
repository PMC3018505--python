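"""Posterior post-processing: similarity matrix, representative partition,
per-group risks, exceedance probabilities, odds ratios and profile deviations.

All summaries are functions of label-invariant trace quantities (co-clustering
counts, per-subject risks, completed-covariate draws), so they are unaffected
by label switching in the mixture sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ProfileDataset
from .sampler import PosteriorTrace

__all__ = [
    "build_similarity", "coclustering_counts", "best_partition",
    "group_risk_posterior", "exceedance_probs", "posterior_or",
    "profile_deviation_intervals", "fit_residual_score", "summarize_groups",
    "BestPartition",
]

HIGH_RISK_PROB = 0.9  # exceedance probability flagging a high/low-risk group


# ---------------------------------------------------------------------------
# similarity matrix


def coclustering_counts(z_draws: np.ndarray) -> np.ndarray:
    """Pairwise co-clustering counts from a (T, n) array of allocations."""
    Z = np.asarray(z_draws)
    n = Z.shape[1]
    counts = np.zeros((n, n))
    for z in Z:
        counts += z[:, None] == z[None, :]
    return counts


def build_similarity(trace) -> np.ndarray:
    """Posterior co-clustering probabilities S_ij = #(z_i = z_j) / T.

    ``trace`` may be a :class:`PosteriorTrace` or a pair
    ``(coclust_counts, n_retained)``. The result is symmetric with unit
    diagonal, and invariant to cluster relabelling by construction.
    """
    if isinstance(trace, PosteriorTrace):
        counts, T = trace.coclust, trace.n_retained
    else:
        counts, T = trace
    if T <= 0:
        raise ValueError("zero retained iterations")
    S = np.asarray(counts, dtype=float) / float(T)
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    return S


# ---------------------------------------------------------------------------
# best partition


@dataclass
class BestPartition:
    labels: np.ndarray        # (n,) group ids 0..G-1, relabelled by size
    n_groups: int
    group_sizes: np.ndarray
    score: float              # least-squares discrepancy to S


def partition_score(S: np.ndarray, labels: np.ndarray) -> float:
    """Sum over i<j of (S_ij - A_ij)^2 with A the partition's co-membership."""
    A = labels[:, None] == labels[None, :]
    d = (S - A) ** 2
    iu = np.triu_indices_from(S, k=1)
    return float(d[iu].sum())


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel groups by decreasing size (ties by first appearance)."""
    uniq, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    first = np.array([int(np.argmax(inv == u)) for u in range(uniq.size)])
    order = np.lexsort((first, -counts))
    rank = np.empty(uniq.size, dtype=np.int64)
    rank[order] = np.arange(uniq.size)
    return rank[inv]


def _pam(D: np.ndarray, G: int, start: int) -> np.ndarray:
    """Deterministic partitioning-around-medoids from a forced first medoid
    with farthest-point completion of the seed set."""
    n = D.shape[0]
    medoids = [start]
    while len(medoids) < G:
        dmin = D[:, medoids].min(axis=1)
        dmin[medoids] = -np.inf
        medoids.append(int(np.argmax(dmin)))
    medoids = np.array(sorted(medoids))
    for _ in range(100):
        labels = np.argmin(D[:, medoids], axis=1)
        labels[medoids] = np.arange(len(medoids))  # medoids stay in their group
        new = medoids.copy()
        for g in range(len(medoids)):
            members = np.where(labels == g)[0]
            cost = D[np.ix_(members, members)].sum(axis=0)
            new[g] = members[int(np.argmin(cost))]
        if np.array_equal(new, medoids):
            break
        medoids = new
    return labels


_PAIR_MOVE_LIMIT = 60  # joint two-subject moves only on small instances


def _greedy_refine(S: np.ndarray, labels: np.ndarray, G_max: int) -> np.ndarray:
    """Local search on the least-squares score: single-subject relocations,
    plus joint two-subject relocations on small instances.

    Uses the pair cost B_ij = 1 - 2 S_ij (the score change of putting i and j
    together rather than apart): moving subject i to group g changes the score
    by C_ig - C_i,old with C_ig = sum_{k in g} B_ik, maintained incrementally.
    Deterministic (index order, strict improvement), run to a fixed point.
    """
    labels = labels.copy()
    n = S.shape[0]
    B = 1.0 - 2.0 * S
    np.fill_diagonal(B, 0.0)
    onehot = np.zeros((n, G_max))
    onehot[np.arange(n), labels] = 1.0
    C = B @ onehot                      # C[i, g] = sum_{k in g} B_ik

    def move(i: int, g: int) -> None:
        C[:, labels[i]] -= B[:, i]
        C[:, g] += B[:, i]
        labels[i] = g

    pair_moves = n <= _PAIR_MOVE_LIMIT
    for _ in range(300):
        changed = False
        for i in range(n):
            gi = labels[i]
            d = C[i] - C[i, gi]
            g = int(np.argmin(d))
            if d[g] < -1e-12:
                move(i, g)
                changed = True
        if pair_moves:
            for i in range(n):
                for j in range(i + 1, n):
                    gi, gj = labels[i], labels[j]
                    bij = B[i, j]
                    # costs excluding the i-j pair itself
                    old = (C[i, gi] - (bij if gj == gi else 0.0)
                           + C[j, gj] - (bij if gi == gj else 0.0)
                           + (bij if gi == gj else 0.0))
                    best_g, best_d = -1, -1e-12
                    for g in range(G_max):
                        if gi == g and gj == g:
                            continue
                        new = (C[i, g] - (bij if gj == g else 0.0)
                               + C[j, g] - (bij if gi == g else 0.0) + bij)
                        if new - old < best_d:
                            best_g, best_d = g, new - old
                    if best_g >= 0:
                        move(i, best_g)
                        move(j, best_g)
                        changed = True
        if not changed:
            break
    return labels


def _partitions_upto(n: int, max_blocks: int):
    """All set partitions of range(n) with at most ``max_blocks`` blocks,
    as restricted-growth label vectors."""
    labels = np.zeros(n, dtype=np.int64)

    def rec(i: int, kmax: int):
        if i == n:
            yield labels.copy()
            return
        for g in range(min(kmax + 1, max_blocks)):
            labels[i] = g
            yield from rec(i + 1, max(kmax, g + 1))

    yield from rec(1, 1)


def best_partition(S: np.ndarray, G_range=None, method: str = "auto") -> BestPartition:
    """Deterministic representative partition closest to the similarity matrix.

    For each candidate number of groups G, partitioning-around-medoids on the
    dissimilarity 1 - S (deterministic farthest-point initialisation) followed
    by a greedy relocation refinement; the partition minimising the
    least-squares discrepancy sum_{i<j} (S_ij - A_ij)^2 over the whole G range
    is returned (ties towards fewer groups). With ``method='auto'`` instances
    of at most 8 subjects are solved exactly by enumerating all set
    partitions; ``method='pam'`` forces the heuristic, ``method='exact'`` the
    enumeration.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("S must be square")
    if G_range is None:
        G_range = range(1, min(n, 10) + 1)
    G_list = sorted(set(int(g) for g in G_range))
    if not G_list or G_list[0] < 1:
        raise ValueError("G_range must contain integers >= 1")
    G_list = [g for g in G_list if g <= n]

    if method == "auto":
        method = "exact" if n <= 8 else "pam"

    if method == "exact":
        best_labels, best_score = None, np.inf
        for labels in _partitions_upto(n, max(G_list)):
            if int(labels.max() + 1) not in G_list:
                continue
            sc = partition_score(S, labels)
            if sc < best_score - 1e-12:
                best_labels, best_score = labels.copy(), sc
    elif method == "pam":
        D = 1.0 - S
        np.fill_diagonal(D, 0.0)
        Gmax = max(G_list)
        starts = (range(n) if n <= 12
                  else [int(i) for i in np.linspace(0, n - 1, 5)])
        candidates = [np.zeros(n, dtype=np.int64)]
        raw = {1: np.zeros(n, dtype=np.int64)}
        for G in G_list:
            if G == 1:
                continue
            for s0 in starts:
                lab = _pam(D, G, s0)
                raw.setdefault(G, lab)
                candidates.append(lab)
        best_labels, best_score = None, np.inf
        for lab in candidates:
            lab = _greedy_refine(S, lab, Gmax)
            if int(np.unique(lab).size) not in G_list:
                continue
            sc = partition_score(S, lab)
            if sc < best_score - 1e-12:
                best_labels, best_score = lab, sc
        if best_labels is None:
            # refinement left no candidate with an admissible block count;
            # fall back to the unrefined PAM partition at the smallest G
            best_labels = raw[min(raw)]
            best_score = partition_score(S, best_labels)
    else:
        raise ValueError(f"unknown method {method!r}")

    labels = _canonical(best_labels)
    sizes = np.bincount(labels)
    return BestPartition(labels=labels, n_groups=int(labels.max() + 1),
                         group_sizes=sizes, score=float(best_score))


# ---------------------------------------------------------------------------
# group-level posterior summaries


def group_risk_posterior(trace: PosteriorTrace, labels: np.ndarray):
    """Per-iteration average risk of each group, and of the whole sample.

    Returns ``(group_draws, overall_draws)`` with shapes (T, G) and (T,).
    The group draw at iteration t is the mean of the per-subject risks
    r_i(t) over the group's members, so its spread reflects how stably the
    sampler co-clusters those subjects.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != trace.n:
        raise ValueError("partition labels do not cover the trace's subjects")
    G = int(labels.max() + 1)
    sizes = np.bincount(labels, minlength=G)
    if np.any(sizes == 0):
        raise ValueError("empty group in partition")
    R = trace.risks
    group_draws = np.stack([R[:, labels == g].mean(axis=1) for g in range(G)],
                           axis=1)
    return group_draws, R.mean(axis=1)


def exceedance_probs(group_draws: np.ndarray, overall_draws: np.ndarray):
    """P(theta_g > theta_bar) and P(theta_g < theta_bar) per group.

    Strict inequalities; exact ties (measure zero for continuous risks)
    count towards neither side.
    """
    gd = np.asarray(group_draws)
    ov = np.asarray(overall_draws)[:, None]
    if gd.shape[0] != ov.shape[0]:
        raise ValueError("draw counts differ")
    p_gt = (gd > ov).mean(axis=0)
    p_lt = (gd < ov).mean(axis=0)
    return p_gt, p_lt


def posterior_or(group_draws: np.ndarray, reference_draws: np.ndarray,
                 level: float = 0.95) -> dict:
    """Posterior of the odds ratio between a group and a reference group.

    Computed per iteration as OR(t) = [theta_g(t) (1 - theta_ref(t))] /
    [theta_ref(t) (1 - theta_g(t))]; summarised by the posterior mean, an
    equal-tailed credible interval, and P(OR > 1).
    """
    g = np.asarray(group_draws, dtype=float)
    r = np.asarray(reference_draws, dtype=float)
    if np.any((g <= 0) | (g >= 1) | (r <= 0) | (r >= 1)):
        raise ValueError("risk draws must lie strictly inside (0, 1)")
    ors = (g * (1.0 - r)) / (r * (1.0 - g))
    lo, hi = np.quantile(ors, [(1 - level) / 2, 1 - (1 - level) / 2])
    return {"mean": float(ors.mean()), "ci": (float(lo), float(hi)),
            "p_gt_1": float((ors > 1.0).mean()), "draws": ors}


def profile_deviation_intervals(trace: PosteriorTrace, labels: np.ndarray,
                                data: ProfileDataset,
                                level: float = 0.95) -> pd.DataFrame:
    """Credible intervals for each group's category-probability deviations.

    For every group g, covariate p and category x, the per-iteration
    difference between the group's empirical frequency of category x (over
    the imputation-completed covariates of the group's members) and the
    whole-sample frequency; summarised by an equal-tailed interval and
    classified as ``positive`` / ``negative`` (interval excludes zero) or
    ``null`` (interval contains zero) — the red/blue/green convention of
    profile plots.
    """
    if trace.X_imp_draws is None:
        raise ValueError("trace does not retain completed-covariate draws "
                         "(store_imputed=False)")
    labels = np.asarray(labels)
    G = int(labels.max() + 1)
    a = (1 - level) / 2
    rows = []
    for p, spec in enumerate(data.specs):
        Xp = trace.X_imp_draws[:, :, p]          # (T, n)
        M = spec.n_categories
        onehot = [(Xp == m) for m in range(M)]
        overall = [oh.mean(axis=1) for oh in onehot]      # (T,) each
        for g in range(G):
            mask = labels == g
            for m in range(M):
                diff = onehot[m][:, mask].mean(axis=1) - overall[m]
                lo, hi = np.quantile(diff, [a, 1 - a])
                cls = ("positive" if lo > 0 else
                       "negative" if hi < 0 else "null")
                rows.append({"group": g, "covariate": spec.name, "category": m,
                             "mean": float(diff.mean()), "lo": float(lo),
                             "hi": float(hi), "class": cls})
    return pd.DataFrame(rows)


def fit_residual_score(p_hat: np.ndarray, y: np.ndarray) -> float:
    """Sum of squared outcome residuals, sum_i (y_i - p_hat_i)^2.

    A model-agnostic fit score comparable across models fitted to the same
    subjects; for the profile-regression fit, ``p_hat`` is the posterior-mean
    per-subject risk. Lower is better.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(((y - p_hat) ** 2).sum())


def summarize_groups(trace: PosteriorTrace, labels: np.ndarray,
                     reference: str | int = "lowest",
                     level: float = 0.95) -> pd.DataFrame:
    """Per-group posterior risk table with exceedance probabilities and ORs.

    ``reference`` is the group index used as the odds-ratio baseline, or
    ``"lowest"`` for the group with the lowest posterior-mean risk.
    """
    gd, ov = group_risk_posterior(trace, labels)
    G = gd.shape[1]
    means = gd.mean(axis=0)
    ref = int(np.argmin(means)) if reference == "lowest" else int(reference)
    p_gt, p_lt = exceedance_probs(gd, ov)
    a = (1 - level) / 2
    rows = []
    for g in range(G):
        o = posterior_or(gd[:, g], gd[:, ref], level)
        lo, hi = np.quantile(gd[:, g], [a, 1 - a])
        rows.append({
            "group": g, "size": int((np.asarray(labels) == g).sum()),
            "theta_mean": float(means[g]), "theta_lo": float(lo),
            "theta_hi": float(hi), "p_above_avg": float(p_gt[g]),
            "p_below_avg": float(p_lt[g]),
            "or_vs_ref": o["mean"], "or_lo": o["ci"][0], "or_hi": o["ci"][1],
            "p_or_gt_1": o["p_gt_1"], "reference": ref,
            "risk_class": ("high" if p_gt[g] > HIGH_RISK_PROB else
                           "low" if p_lt[g] > HIGH_RISK_PROB else "average"),
        })
    return pd.DataFrame(rows)
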