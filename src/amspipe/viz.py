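"""Evaluation plots (SVG): ROC, calibration, SHAP beeswarm, decision curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def plot_roc(roc_points, auc, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc_points["fpr"], roc_points["tpr"], lw=2,
            label=f"AUC = {auc:.2f}")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_calibration(calibration, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(calibration["mean_predicted"], calibration["observed_rate"],
            "o-", lw=1.5)
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
    ax.set_xlabel("Mean predicted probability")
    ax.set_ylabel("Observed event rate")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_shap_beeswarm(shap_values, feature_values, feature_names, path,
                       seed: int = 0) -> None:
    rng = np.random.default_rng(seed)
    order = np.argsort(np.abs(shap_values).mean(axis=0))
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(feature_names) + 1.5))
    for row, j in enumerate(order):
        sv = shap_values[:, j]
        fv = feature_values[:, j]
        rank = (fv - fv.min()) / (np.ptp(fv) or 1.0)
        jitter = rng.normal(0, 0.08, size=sv.size)
        ax.scatter(sv, np.full_like(sv, row) + jitter, c=rank, cmap="coolwarm",
                   s=12, alpha=0.8)
    ax.axvline(0, color="grey", lw=1)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([feature_names[j] for j in order], fontsize=8)
    ax.set_xlabel("SHAP value")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_dca(dca, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, grp in dca.groupby("model"):
        style = "--" if name in ("treat_all", "treat_none") else "-"
        ax.plot(grp["threshold"], grp["net_benefit"], style, label=name, lw=1.5)
    ax.set_ylim(bottom=-0.1)
    ax.set_xlabel("Threshold probability")
    ax.set_ylabel("Net benefit")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_all(out_dir, train_eval, dca_train, shap_matrix, feature_names,
             panel_train) -> None:
    out = Path(out_dir)
    plot_roc(train_eval.roc_points, train_eval.auc, out / "roc.svg")
    plot_calibration(train_eval.calibration, out / "calibration.svg")
    if dca_train is not None:
        plot_dca(dca_train, out / "dca.svg")
    if shap_matrix is not None:
        plot_shap_beeswarm(shap_matrix, panel_train.to_numpy(dtype=float),
                           list(feature_names), out / "shap_beeswarm.svg")
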