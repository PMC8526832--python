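"""Optional figure helpers (matplotlib): calibration bands, rejection curves,
and predictive-std boxplots.  Imported lazily so the core library has no hard
plotting dependency."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .evaluation import UncertaintySplit


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_calibration(calibration, path: str | Path) -> None:
    """Reliability diagram with the 95% epistemic band."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 4))
    centers = 0.5 * (calibration.bin_low + calibration.bin_high)
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect")
    ax.plot(centers, calibration.fraction_positive, "o-", label="mean curve")
    ax.fill_between(centers, calibration.band_low, calibration.band_high,
                    alpha=0.3, label="95% band")
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("fraction positive")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rejection_curves(confidence_table, path: str | Path) -> None:
    """Accuracy and AUROC against the confidence threshold."""
    plt = _plt()
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    t = confidence_table
    axes[0].plot(t.threshold, t.accuracy, "o-")
    axes[0].set_xlabel("confidence threshold")
    axes[0].set_ylabel("accuracy")
    axes[1].plot(t.threshold, t.auroc, "o-")
    axes[1].set_xlabel("confidence threshold")
    axes[1].set_ylabel("AUROC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_std_boxplots(split: UncertaintySplit, path: str | Path) -> None:
    """Predictive-std distributions for TP/FP and TN/FN."""
    plt = _plt()
    fig, axes = plt.subplots(1, 2, figsize=(7, 3.5), sharey=True)
    axes[0].boxplot([split.tp, split.fp], tick_labels=["TP", "FP"])
    axes[0].set_title("positive predictions")
    axes[0].set_ylabel("predictive std")
    axes[1].boxplot([split.tn, split.fn], tick_labels=["TN", "FN"])
    axes[1].set_title("negative predictions")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
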