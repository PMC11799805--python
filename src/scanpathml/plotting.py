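"""Scanpath rendering (convenience visualization)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless, deterministic
import matplotlib.pyplot as plt
import numpy as np

from .gaze_model import Trial


def render_scanpath(
    trial: Trial,
    out_path: str | Path,
    image: np.ndarray | None = None,
    grid: tuple[int, int] | None = None,
) -> Path:
    """Render a trial's scanpath to a PNG.

    Fixations are drawn in temporal order along a connecting path; the
    first fixation is marked with a cross, the last with a star.  An
    optional ``grid=(grid_x, grid_y)`` overlays the encoder's cell
    boundaries; an optional grayscale ``image`` is drawn underneath.
    """
    if not trial.fixations:
        raise ValueError("cannot render an empty trial")
    out_path = Path(out_path)
    w, h = trial.display_w, trial.display_h
    xy = trial.xy

    fig, ax = plt.subplots(figsize=(6, 6 * h / w))
    if image is not None:
        ax.imshow(image, cmap="gray", extent=(0, w, h, 0))
    ax.plot(xy[:, 0], xy[:, 1], "-", color="tab:gray", lw=0.8, zorder=1)
    ax.scatter(xy[:, 0], xy[:, 1], s=30, marker="s", facecolor="gold",
               edgecolor="red", linewidths=0.6, zorder=2)
    ax.scatter(*xy[0], s=90, marker="x", color="blue", zorder=3, label="first")
    ax.scatter(*xy[-1], s=120, marker="*", color="magenta", zorder=3, label="last")
    if grid is not None:
        gx, gy = grid
        for j in range(1, gx):
            ax.axvline(j * w / gx, color="k", lw=0.5, alpha=0.5)
        for i in range(1, gy):
            ax.axhline(i * h / gy, color="k", lw=0.5, alpha=0.5)
    ax.set_xlim(0, w)
    ax.set_ylim(h, 0)  # y grows downward
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"{trial.trial_id} ({trial.label})")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100, metadata={"Software": "scanpathml"})
    plt.close(fig)
    return out_path
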