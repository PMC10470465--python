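"""Wireframe preview rendering (line drawings of projected stimuli)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["render_wireframe", "render_trajectory_frames"]


def render_wireframe(
    snapshot2d: np.ndarray,
    edges: np.ndarray,
    path: str | Path,
    *,
    figsize: tuple[float, float] = (4, 4),
    invert_y: bool = True,
) -> None:
    """Draw a 2D vertex snapshot with its edges to a PNG file.

    ``invert_y`` flips the vertical axis so that image coordinates
    (y downward) render upright.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    snapshot2d = np.asarray(snapshot2d, dtype=float)
    fig, ax = plt.subplots(figsize=figsize)
    for a, b in np.asarray(edges, dtype=int):
        ax.plot(
            [snapshot2d[a, 0], snapshot2d[b, 0]],
            [snapshot2d[a, 1], snapshot2d[b, 1]],
            color="black",
            linewidth=1,
        )
    ax.set_aspect("equal")
    if invert_y:
        ax.invert_yaxis()
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def render_trajectory_frames(
    frames2d: np.ndarray,
    edges: np.ndarray,
    out_dir: str | Path,
    *,
    stride: int = 10,
    prefix: str = "frame",
) -> list[Path]:
    """Render every ``stride``-th 2D frame as PNG; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for t in range(0, frames2d.shape[0], stride):
        p = out_dir / f"{prefix}_{t:04d}.png"
        render_wireframe(frames2d[t], edges, p)
        written.append(p)
    return written
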