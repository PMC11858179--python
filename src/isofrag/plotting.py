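"""Minimal plotting helpers: SY/breakdown curves and PCA score/loading plots."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .chemometrics import PcaModel
from .energy import SurvivalYieldCurve


def plot_curves(
    curves: Sequence[SurvivalYieldCurve],
    path: str | Path,
    ylabel: str = "fraction of TIC",
) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for c in curves:
        label = c.peptide_id
        target = getattr(c, "target_mz", None)
        if target is not None and target == target:  # not NaN
            label = f"{c.peptide_id} m/z {target:.2f}"
        ax.plot(c.voltages, c.values, marker="o", label=label)
    ax.set_xlabel("acceleration voltage (V)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scores(
    model: PcaModel, labels: Sequence[str], path: str | Path
) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    groups = sorted(set(labels))
    for g in groups:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        ax.scatter(model.scores[idx, 0], model.scores[idx, 1], label=g, s=25)
    ax.set_xlabel(f"PC1 ({model.explained_variance_pct[0]:.2f}%)")
    ax.set_ylabel(f"PC2 ({model.explained_variance_pct[1]:.2f}%)")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_loadings(model: PcaModel, path: str | Path, annotate_top: int = 8) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(model.loadings[:, 0], model.loadings[:, 1], s=12)
    import numpy as np

    mags = np.linalg.norm(model.loadings[:, :2], axis=1)
    for i in np.argsort(mags)[::-1][:annotate_top]:
        ax.annotate(
            f"{model.variable_mzs[i]:.2f}",
            (model.loadings[i, 0], model.loadings[i, 1]),
            fontsize=6,
        )
    ax.set_xlabel("PC1 loading")
    ax.set_ylabel("PC2 loading")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
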