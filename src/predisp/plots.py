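"""Figures: validation-loss curves and the 2-D latent embedding."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_validation_curves", "plot_latent_embedding"]


def plot_validation_curves(curves: dict, baselines: dict | None, path) -> Path:
    """Per-epoch validation latent-MSE of each trained predictor.

    Horizontal lines mark the static initializer baselines the learned
    models must undercut.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    for kind, curve in curves.items():
        ax.plot(curve["epoch"], curve["val_mse"], label=kind)
    if baselines:
        for name, mse in baselines.items():
            ax.axhline(mse, ls="--", lw=1, color="grey")
            ax.annotate(name, (0.02, mse), fontsize=8, va="bottom")
    ax.set_xlabel("epoch")
    ax.set_ylabel("validation latent MSE")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_latent_embedding(embedding: np.ndarray, path, connect: bool = True) -> Path:
    """Scatter of latent codes on their top-2 principal axes.

    With ``connect`` the temporal order is drawn as a faint path, making the
    frame-to-frame coherence of the trajectory visible.
    """
    emb = np.asarray(embedding)
    fig, ax = plt.subplots(figsize=(5, 5))
    if connect:
        ax.plot(emb[:, 0], emb[:, 1], "-", lw=0.5, alpha=0.4, color="grey")
    sc = ax.scatter(emb[:, 0], emb[:, 1], c=np.arange(len(emb)), s=12, cmap="viridis")
    fig.colorbar(sc, ax=ax, label="frame")
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
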