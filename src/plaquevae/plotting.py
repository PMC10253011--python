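"""Figures: latent scatter with class boundaries, per-slice class maps."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classify import CLASS_LABELS, ClassBoundaries, LesionReport

__all__ = ["latent_scatter", "class_map_strip", "loss_curves"]

_CLASS_COLORS = {1: "#2ca02c", 2: "#1f77b4", 3: "#9467bd", 4: "#262626"}


def latent_scatter(
    points: np.ndarray,
    classes: Sequence[int],
    boundaries: ClassBoundaries | None = None,
    path: str | Path | None = None,
):
    """Scatter of latent points colored by tissue class, with the two
    rectangular decision thresholds drawn in red."""
    pts = np.asarray(points, dtype=float)
    classes = np.asarray(list(classes), dtype=int)
    fig, ax = plt.subplots(figsize=(6, 6))
    for c in (1, 2, 3, 4):
        sel = classes == c
        if sel.any():
            ax.scatter(
                pts[sel, 0],
                pts[sel, 1],
                s=8,
                color=_CLASS_COLORS[c],
                label=f"class {c}: {CLASS_LABELS[c]}",
                alpha=0.7,
            )
    if boundaries is not None:
        ax.axvline(boundaries.x_threshold, color="red", lw=1.5)
        ax.axhline(boundaries.y_threshold, color="red", lw=1.5)
    ax.set_xlabel("latent x")
    ax.set_ylabel("latent y")
    ax.legend(fontsize=8, loc="best")
    ax.set_title("Latent space with tissue-class boundaries")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)
    return fig


def class_map_strip(report: LesionReport, path: str | Path | None = None):
    """Greyscale-coded per-slice tissue-class strip along the lesion.

    Darker grey = higher tissue score (more hard tissue)."""
    grey = {1: 1.0, 2: 0.75, 3: 0.45, 4: 0.1}
    vals = np.array([[grey[c] for c in report.per_slice_class]])
    fig, ax = plt.subplots(figsize=(8, 1.6))
    ax.imshow(vals, cmap="gray", vmin=0, vmax=1, aspect="auto")
    ax.set_yticks([])
    ax.set_xlabel("axial slice index")
    ax.set_title(
        f"{report.lesion_id}: average tissue score "
        f"{report.average_tissue_score:.2f}"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)
    return fig


def loss_curves(loss_trace, path: str | Path | None = None):
    """Reconstruction and KL loss terms per epoch."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(loss_trace.index, loss_trace["recon"], label="reconstruction MSE")
    ax2 = ax.twinx()
    ax2.plot(loss_trace.index, loss_trace["kl"], color="C1", label="KL")
    ax.set_xlabel("epoch")
    ax.set_ylabel("reconstruction MSE")
    ax2.set_ylabel("KL divergence")
    ax.legend(loc="upper right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)
    return fig
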