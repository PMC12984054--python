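"""Diagnostic figures: ROC curves, calibration, decision curves (SVG)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .evaluation_stats import auc_delong, decision_curve


def plot_roc_curves(
    predictions: dict[str, pd.DataFrame], split: str, path: str | Path
) -> Path:
    """One ROC curve per model for a cohort split."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, preds in predictions.items():
        grp = preds[preds["split"] == split]
        if grp["label"].nunique() < 2:
            continue
        fpr, tpr, _ = roc_curve(grp["label"], grp["probability"])
        auc = auc_delong(grp["probability"], grp["label"]).auc
        ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC — {split}")
    ax.legend(fontsize=8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return path


def plot_decision_curves(
    predictions: dict[str, pd.DataFrame], split: str, path: str | Path
) -> Path:
    """Net-benefit curves with treat-all/treat-none references."""
    fig, ax = plt.subplots(figsize=(5, 4))
    reference_drawn = False
    grid = np.linspace(0.0, 0.6, 61)
    for name, preds in predictions.items():
        grp = preds[preds["split"] == split]
        if grp["label"].nunique() < 2:
            continue
        df = decision_curve(grp["probability"].to_numpy(), grp["label"].to_numpy(), grid)
        ax.plot(df["threshold"], df["net_benefit"], label=name)
        if not reference_drawn:
            ax.plot(df["threshold"], df["treat_all"], "k:", label="treat all")
            ax.plot(df["threshold"], df["treat_none"], "k--", label="treat none")
            reference_drawn = True
    ax.set_ylim(bottom=-0.05)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_title(f"Decision curves — {split}")
    ax.legend(fontsize=8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return path


def plot_calibration(
    predictions: dict[str, pd.DataFrame], split: str, path: str | Path, bins: int = 10
) -> Path:
    """Observed vs predicted risk by decile of predicted probability."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, preds in predictions.items():
        grp = preds[preds["split"] == split]
        p = grp["probability"].to_numpy()
        y = grp["label"].to_numpy()
        edges = np.quantile(p, np.linspace(0, 1, bins + 1)[1:-1])
        g = np.digitize(p, edges)
        xs, ys = [], []
        for b in np.unique(g):
            sel = g == b
            xs.append(p[sel].mean())
            ys.append(y[sel].mean())
        ax.plot(xs, ys, "o-", ms=3, label=name)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed frequency")
    ax.set_title(f"Calibration — {split}")
    ax.legend(fontsize=8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return path
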