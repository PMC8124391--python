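"""Blood-flow velocimetry by spatial-temporal analysis (STA).

A moving red-blood-cell cluster darkens successive positions along a vessel
centerline.  Stacking the centerline intensity profile of every frame as a
column produces the STA image (a kymograph): position along the vessel on
the rows, time on the columns.  A cluster moving at constant speed traces a
straight dark streak whose slope (rows per frame) converts to velocity via
the optical scale and frame rate,

    v [mm/s] = slope [px/frame] * row_scale [um/px] * fps / 1000.

Not every vessel shows measurable flow.  Vessels are ranked by an
*observability index* combining the temporal intensity variance along the
centerline (flow produces fluctuation) and the segment length (longer
vessels give longer streaks):

    index = alpha * sigma_t_hat + beta * L_hat,

with both terms min-max normalized across segments; the top-k segments
(default 15) are analyzed.

Slopes are found automatically: the background is removed by subtracting
each row's temporal median, then a slope grid is scanned and each candidate
slope "deskews" the image (shifting column t by slope * t rows); the true
streak slope aligns all streaks horizontally and maximizes the variance of
the row-mean profile.  Peaks of that profile are the individual streaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import FrameSequence
from .morphology import (
    VesselGraph,
    VesselSegment,
    extract_segments,
    segment_diameter,
    skeletonize,
)

__all__ = [
    "observability_rank",
    "build_sta",
    "estimate_slopes",
    "slopes_from_endpoints",
    "velocity_from_slopes",
    "measure_velocities",
    "ObservabilityRanking",
    "STAImage",
    "VelocityEstimate",
]


@dataclass
class ObservabilityRanking:
    segment_ids: list[int]
    sigma_t: np.ndarray
    length_px: np.ndarray
    index: np.ndarray
    selected_ids: list[int]


@dataclass
class STAImage:
    """Centerline intensity stacked per frame (rows = position, cols = time)."""

    matrix: np.ndarray
    row_scale_um: float          # microns advanced along the vessel per row
    col_scale_s: float           # nominal seconds per column (1 / fps)
    segment_id: int
    col_positions: np.ndarray = None  # original frame index of each column

    def __post_init__(self):
        if self.col_positions is None:
            self.col_positions = np.arange(self.matrix.shape[1], dtype=float)
        else:
            self.col_positions = np.asarray(self.col_positions, dtype=float)


@dataclass
class VelocityEstimate:
    slopes_px_per_frame: list[float]
    velocity_mm_s: Optional[float]
    n_streaks: int
    quality: float


def observability_rank(
    seq: FrameSequence,
    graph: VesselGraph,
    alpha: float = 0.5,
    beta: float = 0.5,
    k: int = 15,
) -> ObservabilityRanking:
    """Rank vessel segments by observability and select the top ``k``."""
    if len(seq) < 2:
        raise ValueError("temporal variance needs at least 2 frames")
    if len(graph.segments) == 0:
        raise ValueError("empty vessel graph")
    sig = np.empty(len(graph.segments))
    L = np.empty(len(graph.segments))
    for j, seg in enumerate(graph.segments):
        traces = seq.frames[:, seg.pixels[:, 0], seg.pixels[:, 1]]  # (T, n)
        sig[j] = float(np.mean(np.var(traces, axis=0)))
        L[j] = seg.length_px

    def minmax(v):
        lo, hi = v.min(), v.max()
        return np.ones_like(v) if hi == lo else (v - lo) / (hi - lo)

    index = alpha * minmax(sig) + beta * minmax(L)
    ids = [s.id for s in graph.segments]
    order = sorted(range(len(ids)), key=lambda j: (-index[j], ids[j]))
    selected = [ids[j] for j in order[: min(k, len(ids))]]
    return ObservabilityRanking(ids, sig, L, index, selected)


def build_sta(seq: FrameSequence, segment: VesselSegment) -> STAImage:
    """Stack the segment's centerline intensities of every frame as columns.

    The row scale accounts for diagonal chain steps: it is the segment's
    Euclidean arc length divided by (n_pixels - 1), in microns, so slopes in
    rows/frame convert to physical speed without orientation bias.  Column
    positions carry each frame's original acquisition index, so sequences
    with rejected frames keep true timing.
    """
    h, w = seq.frame_shape
    px = segment.pixels
    if px[:, 0].min() < 0 or px[:, 0].max() >= h or px[:, 1].min() < 0 or px[:, 1].max() >= w:
        bad = int(np.argmax((px[:, 0] < 0) | (px[:, 0] >= h) | (px[:, 1] < 0) | (px[:, 1] >= w)))
        raise ValueError(f"centerline pixel {tuple(px[bad])} outside {h}x{w} frames")
    matrix = seq.frames[:, px[:, 0], px[:, 1]].T.copy()  # (n_pixels, T)
    n = len(px)
    step = segment.smoothed_arc_length_px() / (n - 1) if n > 1 else 1.0
    rel = seq.frame_indices - seq.frame_indices[0]
    return STAImage(
        matrix=matrix,
        row_scale_um=seq.microns_per_pixel * step,
        col_scale_s=1.0 / seq.fps,
        segment_id=segment.id,
        col_positions=rel.astype(float),
    )


def _deskew_profile(amp: np.ndarray, cols: np.ndarray, slope: float) -> np.ndarray:
    """Row-mean profile after shifting column t up by slope * cols[t] rows.

    Rows wrap modulo the image height, so every row stays fully covered at
    every candidate slope (unwrapped shifting would leave steep slopes with
    few samples per row, biasing the variance score upward).
    """
    n_rows, n_cols = amp.shape
    rows = np.arange(n_rows, dtype=float)[:, None]
    pos = np.mod(rows + slope * cols[None, :], n_rows)
    i0 = np.floor(pos).astype(int) % n_rows
    i1 = (i0 + 1) % n_rows
    frac = pos - np.floor(pos)
    tidx = np.broadcast_to(np.arange(n_cols), pos.shape)
    vals = amp[i0, tidx] * (1.0 - frac) + amp[i1, tidx] * frac
    return vals.mean(axis=1)


def estimate_slopes(
    sta: STAImage,
    slope_range: tuple[float, float] = (0.15, 25.0),
    n_coarse: int = 120,
    min_snr: float = 3.0,
    peak_rel_prominence: float = 0.3,
) -> VelocityEstimate:
    """Detect streaks in an STA image and estimate their common slope.

    Returns an empty slope list when no orientation stands out from the
    background (the velocity is then reported missing, not zero).
    """
    A = np.asarray(sta.matrix, dtype=float)
    if A.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    detrended = A - np.median(A, axis=1, keepdims=True)
    amp = np.maximum(-detrended, 0.0)  # dark streaks -> positive amplitude
    if amp.max() <= 0:
        return VelocityEstimate([], None, 0, 0.0)
    cols = sta.col_positions

    grid = np.geomspace(slope_range[0], slope_range[1], n_coarse)
    grid = np.concatenate([-grid[::-1], grid])
    scores = np.array([np.var(_deskew_profile(amp, cols, m)) for m in grid])
    baseline = float(np.median(scores))
    best = int(np.argmax(scores))
    snr = scores[best] / baseline if baseline > 0 else np.inf
    if snr < min_snr:
        return VelocityEstimate([], None, 0, float(snr))

    # local refinement: two shrinking grids then a parabolic vertex
    m = grid[best]
    half = abs(grid[min(best + 1, len(grid) - 1)] - grid[max(best - 1, 0)]) / 2 or abs(m) * 0.1
    for _ in range(2):
        local = np.linspace(m - half, m + half, 21)
        ls = np.array([np.var(_deskew_profile(amp, cols, mm)) for mm in local])
        j = int(np.argmax(ls))
        m = local[j]
        if 0 < j < len(local) - 1:
            y0, y1, y2 = ls[j - 1], ls[j], ls[j + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                m += 0.5 * (y0 - y2) / denom * (local[1] - local[0])
        half /= 10.0

    profile = _deskew_profile(amp, cols, m)
    base = float(np.median(profile))
    prom = peak_rel_prominence * (profile.max() - base)
    peaks, props = find_peaks(profile, prominence=max(prom, 1e-12))
    n_streaks = max(len(peaks), 1)
    slopes = [float(m)] * n_streaks
    return VelocityEstimate(slopes, None, n_streaks, float(snr))


def slopes_from_endpoints(
    endpoints: list[tuple[tuple[float, float], tuple[float, float]]],
) -> VelocityEstimate:
    """Manual mode: one streak slope per user-supplied endpoint pair.

    Each pair is ((row0, col0), (row1, col1)) read off the STA image, e.g.
    from an annotated kymograph; slope = delta_row / delta_col in rows per
    frame-column.
    """
    slopes = []
    for (r0, c0), (r1, c1) in endpoints:
        if c1 == c0:
            raise ValueError("streak endpoints must span at least one column")
        slopes.append((r1 - r0) / (c1 - c0))
    return VelocityEstimate(slopes, None, len(slopes), float("nan"))


def velocity_from_slopes(estimate: VelocityEstimate, sta: STAImage) -> VelocityEstimate:
    """Convert detected slopes to a mean speed in mm/s (magnitude only)."""
    if not estimate.slopes_px_per_frame:
        estimate.velocity_mm_s = None
        return estimate
    v = [
        abs(m) * sta.row_scale_um / sta.col_scale_s / 1000.0
        for m in estimate.slopes_px_per_frame
    ]
    estimate.velocity_mm_s = float(np.mean(v))
    return estimate


def measure_velocities(
    seq: FrameSequence,
    mask: np.ndarray,
    alpha: float = 0.5,
    beta: float = 0.5,
    k: int = 15,
    min_len: int = 20,
    graph: Optional[VesselGraph] = None,
) -> tuple[pd.DataFrame, dict[int, STAImage]]:
    """Full velocimetry on a motion-corrected sequence and vessel mask.

    Skeletonizes the mask, measures segment morphology, ranks observability,
    builds an STA image per selected segment, and estimates velocities.
    Returns a per-vessel table (id, diameter um, length mm, velocity mm/s,
    n_streaks, quality) and the STA images by segment id.
    """
    if graph is None:
        graph = extract_segments(skeletonize(mask), min_len=min_len)
        graph = segment_diameter(graph, mask)
    ranking = observability_rank(seq, graph, alpha=alpha, beta=beta, k=k)
    by_id = {s.id: s for s in graph.segments}
    um_px = seq.microns_per_pixel
    rows, stas = [], {}
    for sid in ranking.selected_ids:
        seg = by_id[sid]
        sta = build_sta(seq, seg)
        est = velocity_from_slopes(estimate_slopes(sta), sta)
        stas[sid] = sta
        rows.append({
            "vessel_id": sid,
            "diameter_um": seg.diameter_px * um_px if seg.diameter_px else None,
            "length_mm": seg.length_px * um_px / 1000.0,
            "velocity_mm_s": est.velocity_mm_s,
            "n_streaks": est.n_streaks,
            "quality": est.quality,
        })
    return pd.DataFrame(rows), stas
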