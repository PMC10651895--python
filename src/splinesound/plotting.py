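"""Plot helpers: spectrogram images, interpolation demos, confusion heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .timefreq import SpectrogramGrid
from .train_eval import ConfusionMatrix

__all__ = ["plot_spectrogram", "plot_confusion", "plot_history"]


def plot_spectrogram(grid: SpectrogramGrid, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    db = 20.0 * np.log10(np.maximum(grid.values, 1e-12) / max(grid.values.max(), 1e-12))
    ax.pcolormesh(grid.col_coords, grid.row_coords, db, shading="auto", cmap="magma")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)" if grid.kind != "scalogram" else "scale (samples)")
    if grid.kind == "scalogram":
        ax.set_yscale("log")
    ax.set_title(title or grid.kind)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def plot_confusion(cm: ConfusionMatrix, path: str | Path) -> None:
    norm = cm.normalized()
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(norm, vmin=0, vmax=1, cmap="Blues")
    ax.set_xticks(range(len(cm.class_names)), cm.class_names, rotation=45, ha="right")
    ax.set_yticks(range(len(cm.class_names)), cm.class_names)
    for i in range(norm.shape[0]):
        for j in range(norm.shape[1]):
            ax.text(j, i, f"{norm[i, j]:.2f}", ha="center", va="center",
                    color="white" if norm[i, j] > 0.5 else "black", fontsize=8)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def plot_history(history, path: str | Path) -> None:
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    for col in ("triplet", "reconstruction", "kl", "total"):
        ax1.plot(history["epoch"], history[col], label=col)
    ax1.set_xlabel("epoch")
    ax1.set_ylabel("loss")
    ax1.legend(fontsize=8)
    ax2.plot(history["epoch"], history["val_accuracy"])
    ax2.set_xlabel("epoch")
    ax2.set_ylabel("validation accuracy")
    ax2.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
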