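"""Lorenz-plot rendering (correlated and de-correlated)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless rendering; import order matters
import matplotlib.pyplot as plt
import numpy as np

from .features import DecorrelationParams, decorrelate, delta_series, lorenz_points
from .rr_io import Window

__all__ = ["plot_lorenz"]


def plot_lorenz(
    window: Window,
    path,
    decorrelated: bool = False,
    params: DecorrelationParams = DecorrelationParams(),
    extent_ms: float = 600.0,
) -> int:
    """Scatter the window's dRR point cloud to an image file.

    Returns the number of points plotted (58 for a 60-beat window).
    """
    pts = lorenz_points(delta_series(window))
    ylabel = r"$\Delta RR[k-1]$ (ms)"
    if decorrelated:
        pts = decorrelate(pts, params)
        ylabel = r"$\Delta RR[k-1] + 0.5\,\Delta RR[k]^{0.75}$ (ms)"
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(pts[:, 0], pts[:, 1], s=12, color="k", alpha=0.7)
    ax.set_xlim(-extent_ms, extent_ms)
    ax.set_ylim(-extent_ms, extent_ms)
    ax.axhline(0, lw=0.5, color="0.7")
    ax.axvline(0, lw=0.5, color="0.7")
    ax.set_xlabel(r"$\Delta RR[k]$ (ms)")
    ax.set_ylabel(ylabel)
    ax.set_title("De-correlated Lorenz plot" if decorrelated
                 else "Lorenz plot")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return pts.shape[0]
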