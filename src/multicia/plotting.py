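"""Optional matplotlib views of the evaluation outputs.

Imported lazily so the core package has no hard plotting dependency;
install the ``plot`` extra to use these helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _mpl():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_roc(roc, path=None, label: str | None = None):
    """Step plot of a relocation ROC curve with its AUC in the legend."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4, 4))
    pts = np.asarray(roc.points)
    ax.plot(pts[:, 0], pts[:, 1], drawstyle="steps-post",
            label=f"{label or 'L1'} (AUC {roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_score_distributions(scores: pd.Series, groups: pd.Series, path=None):
    """Line/strip + box view of one latent variable split by diagnosis group."""
    plt = _mpl()
    groups = groups.reindex(scores.index)
    order = list(dict.fromkeys(groups))
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=True)
    for i, g in enumerate(order):
        vals = scores[groups == g]
        axes[0].plot(np.full(len(vals), i) + np.linspace(-0.15, 0.15, len(vals)),
                     vals, "o", ms=4, label=g)
    axes[0].set_xticks(range(len(order)), order, rotation=45)
    axes[0].set_ylabel("latent score")
    axes[1].boxplot([scores[groups == g].to_numpy() for g in order],
                    tick_labels=order)
    axes[1].tick_params(axis="x", rotation=45)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
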