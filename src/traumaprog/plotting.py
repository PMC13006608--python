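"""Optional figure output: ROC curves, confusion matrices, decision
curves and nomogram calibration.  All numeric results exist as JSON/CSV
first; these helpers only render them."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_roc", "plot_confusion", "plot_decision_curve",
           "plot_calibration"]


def plot_roc(curves: dict[str, tuple[np.ndarray, np.ndarray]],
             path: str | Path) -> Path:
    """One ROC figure with a labelled curve per model."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, (fpr, tpr) in curves.items():
        ax.plot(fpr, tpr, label=label)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_confusion(cm: np.ndarray, labels: list[str], path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(cm, cmap="Blues")
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("observed")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, f"{cm[i, j]:.0f}", ha="center", va="center",
                    color="black", fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_decision_curve(dca: pd.DataFrame, path: str | Path,
                        label: str = "model") -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(dca["threshold"], dca["net_benefit"], label=label)
    ax.plot(dca["threshold"], dca["treat_all"], label="treat all", ls="--")
    ax.plot(dca["threshold"], dca["treat_none"], label="treat none", ls=":")
    ax.set_ylim(bottom=max(-0.1, dca["net_benefit"].min() - 0.02))
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_calibration(curve: pd.DataFrame, path: str | Path) -> Path:
    """Bootstrap calibration curve: observed rate vs predicted probability."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="ideal")
    ax.plot(curve["predicted"], curve["observed"], "o-", label="observed")
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
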