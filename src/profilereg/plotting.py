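"""Plotting helpers: similarity heat map and profile-deviation bar plots."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_similarity", "plot_profile_deviations"]

_CLASS_COLORS = {"positive": "tab:red", "negative": "tab:blue",
                 "null": "tab:green"}


def plot_similarity(S, labels=None, ax=None):
    """Heat map of the posterior co-clustering matrix, optionally ordered by
    a partition's groups."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    S = np.asarray(S)
    if labels is not None:
        order = np.argsort(np.asarray(labels), kind="stable")
        S = S[np.ix_(order, order)]
    im = ax.imshow(S, vmin=0, vmax=1, cmap="viridis", interpolation="nearest")
    ax.figure.colorbar(im, ax=ax, label="co-clustering probability")
    ax.set_xlabel("subject")
    ax.set_ylabel("subject")
    return ax


def plot_profile_deviations(deviations, group: int, ax=None):
    """Bar-with-interval plot of one group's category-probability deviations.

    ``deviations`` is the DataFrame from
    :func:`profilereg.postprocess.profile_deviation_intervals`. Bars are
    coloured red/blue when the 95% interval excludes zero from above/below
    and green otherwise.
    """
    import matplotlib.pyplot as plt

    d = deviations[deviations["group"] == group].reset_index(drop=True)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.35 * len(d)), 4))
    x = np.arange(len(d))
    colors = [_CLASS_COLORS[c] for c in d["class"]]
    ax.bar(x, d["mean"], color=colors, width=0.7)
    ax.errorbar(x, d["mean"], yerr=[d["mean"] - d["lo"], d["hi"] - d["mean"]],
                fmt="none", ecolor="black", capsize=2, lw=0.8)
    ax.axhline(0.0, color="gray", lw=0.8)
    ax.set_xticks(x)
    ax.set_xticklabels([f"{c}:{m}" for c, m in zip(d["covariate"],
                                                   d["category"])],
                       rotation=90, fontsize=7)
    ax.set_ylabel("group minus population category probability")
    ax.set_title(f"group {group}")
    return ax
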