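"""Quick-look plots: kymographs and motion-correction traces."""

from __future__ import annotations

import numpy as np

from .velocimetry import STAImage

__all__ = ["plot_sta", "plot_displacements"]


def plot_sta(sta: STAImage, ax=None, cmap: str = "gray"):
    """Show an STA image (position along the vessel vs time).

    Axes are labeled in physical units using the image's row/column scales.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    n_rows, n_cols = sta.matrix.shape
    extent = (0.0, sta.col_positions[-1] * sta.col_scale_s,
              n_rows * sta.row_scale_um / 1000.0, 0.0)
    ax.imshow(sta.matrix, aspect="auto", cmap=cmap, extent=extent)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("position along vessel (mm)")
    ax.set_title(f"vessel segment {sta.segment_id}")
    return ax


def plot_displacements(displacements_px: np.ndarray, microns_per_pixel: float,
                       ax=None, label: str | None = None):
    """Per-frame displacement magnitude in microns (motion-correction trace)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    d = np.asarray(displacements_px, dtype=float)
    mag = np.hypot(d[:, 0], d[:, 1]) * microns_per_pixel
    ax.plot(mag, label=label)
    ax.set_xlabel("frame")
    ax.set_ylabel("displacement (um)")
    if label:
        ax.legend()
    return ax
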