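"""Synthetic conjunctiva-like video with full ground truth.

Scenes emulate green-light bulbar-conjunctiva recordings: a bright tissue
background with smooth uneven illumination, dark curvilinear microvessels
(nominal diameters 8-16 um at ~0.908 um/px), darker red-blood-cell clusters
translating along each vessel centerline at a constant known speed, global
frame translation composed of rare large jumps (saccades) plus small
sinusoidal drift (respiration), occasional motion-blurred frames, and
additive Gaussian noise.

Everything is rendered on a canvas padded beyond the frame so that global
shifts reveal real tissue rather than empty borders, and all randomness is
driven by a single seed, so an identical configuration reproduces the scene
byte for byte.  The ground truth records the vessel mask, per-vessel
centerlines, diameters and velocities, the applied per-frame displacement,
and which frames were blurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .io import FrameSequence

__all__ = [
    "SceneConfig",
    "Vessel",
    "GroundTruth",
    "generate_vessels",
    "vessel_from_waypoints",
    "render_sequence",
    "generate_scene",
]


@dataclass
class SceneConfig:
    """Scene parameters; defaults target the imaging regime of the real system
    (25 fps, ~0.908 um/px, vessel diameters 8-16 um, speeds 0.05-0.4 mm/s)."""

    frame_shape: tuple[int, int] = (320, 448)     # (H, W) px
    n_frames: int = 70
    fps: float = 25.0
    microns_per_pixel: float = 3.45 / 3.798
    n_vessels: int = 6
    diameter_um_range: tuple[float, float] = (8.0, 16.0)
    velocity_mm_s_range: tuple[float, float] = (0.05, 0.4)
    cluster_len_px: float = 14.0
    cluster_contrast: float = 0.18
    cluster_spacing_px: float = 70.0
    vessel_contrast: float = 0.25
    background: float = 0.85
    illumination_amplitude: float = 0.12
    snr: Optional[float] = 10.0                  # None -> noise-free
    saccades: dict = field(default_factory=lambda: {23: (18, -12), 47: (-22, 15)})
    drift_amplitude_px: float = 5.0
    drift_period_s: float = 2.8
    blur_frames: tuple[int, ...] = (23, 47, 60)
    # blur during a saccadic transition spans a distance comparable to the
    # saccade amplitude itself at this magnification
    blur_len_px: int = 18
    pad: int = 64
    subpixel_motion: bool = False
    seed: int = 0


@dataclass
class Vessel:
    """A single vessel: dense centerline samples in canvas coordinates."""

    points: np.ndarray          # (n, 2) float (row, col), ~0.5 px spacing
    diameter_px: float
    velocity_mm_s: float
    arc: np.ndarray = None      # cumulative arc length at each sample

    def __post_init__(self):
        if self.arc is None:
            steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arc = np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length_px(self) -> float:
        return float(self.arc[-1])

    def point_at(self, a: np.ndarray) -> np.ndarray:
        """Centerline point(s) at arc position(s) ``a`` (wrapped)."""
        a = np.mod(a, self.arc[-1])
        r = np.interp(a, self.arc, self.points[:, 0])
        c = np.interp(a, self.arc, self.points[:, 1])
        return np.stack([r, c], axis=-1)


@dataclass
class GroundTruth:
    mask: np.ndarray                    # (H, W) bool, zero-offset frame region
    vessels: list[Vessel]               # centerlines in frame coordinates
    displacements_px: np.ndarray        # (T, 2) applied content shift (dx, dy)
    blurred_frames: list[int]
    canvas_mask: np.ndarray = None


def vessel_from_waypoints(
    waypoints: Sequence[tuple[float, float]],
    diameter_px: float,
    velocity_mm_s: float = 0.0,
    samples_per_px: float = 2.0,
) -> Vessel:
    """Build a vessel by cubic-spline interpolation through (row, col) waypoints."""
    wp = np.asarray(waypoints, dtype=float)
    if len(wp) < 2:
        raise ValueError("need at least 2 waypoints")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(wp, axis=0), axis=1))])
    if len(wp) == 2:
        n = max(int(chord[-1] * samples_per_px), 2)
        t = np.linspace(0, 1, n)
        pts = wp[0] + t[:, None] * (wp[1] - wp[0])
    else:
        cs_r = CubicSpline(chord, wp[:, 0])
        cs_c = CubicSpline(chord, wp[:, 1])
        n = max(int(chord[-1] * samples_per_px), 2)
        t = np.linspace(0, chord[-1], n)
        pts = np.stack([cs_r(t), cs_c(t)], axis=1)
    return Vessel(points=pts, diameter_px=diameter_px, velocity_mm_s=velocity_mm_s)


def generate_vessels(cfg: SceneConfig, rng: Optional[np.random.Generator] = None,
                     max_retries: int = 50) -> list[Vessel]:
    """Random smooth non-self-intersecting vessels spanning the padded canvas.

    Each vessel runs between two jittered anchor points on opposite canvas
    borders with two interior waypoints displaced perpendicular to the
    chord; mild displacements keep each curve simple, while different
    vessels may cross each other (exercising crossover detection).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    H, W = cfg.frame_shape
    ch, cw = H + 2 * cfg.pad, W + 2 * cfg.pad
    lo_um, hi_um = cfg.diameter_um_range
    lo_v, hi_v = cfg.velocity_mm_s_range
    vessels: list[Vessel] = []
    for _ in range(cfg.n_vessels):
        for attempt in range(max_retries):
            horizontal = rng.random() < 0.5
            if horizontal:
                p0 = np.array([rng.uniform(0.1, 0.9) * ch, 0.0])
                p1 = np.array([rng.uniform(0.1, 0.9) * ch, cw - 1.0])
            else:
                p0 = np.array([0.0, rng.uniform(0.1, 0.9) * cw])
                p1 = np.array([ch - 1.0, rng.uniform(0.1, 0.9) * cw])
            chord = p1 - p0
            norm = np.linalg.norm(chord)
            perp = np.array([-chord[1], chord[0]]) / norm
            mids = [
                p0 + chord * f + perp * rng.uniform(-0.12, 0.12) * norm
                for f in (0.33, 0.66)
            ]
            wp = [p0, *mids, p1]
            d_px = rng.uniform(lo_um, hi_um) / cfg.microns_per_pixel
            v = rng.uniform(lo_v, hi_v)
            vessel = vessel_from_waypoints(wp, diameter_px=d_px, velocity_mm_s=v)
            # reject curves that wander out of the canvas
            if (vessel.points[:, 0].min() >= -1 and vessel.points[:, 0].max() <= ch
                    and vessel.points[:, 1].min() >= -1 and vessel.points[:, 1].max() <= cw):
                vessels.append(vessel)
                break
        else:
            raise RuntimeError("could not place vessels within retry budget")
    return vessels


def _paint_disks(canvas: np.ndarray, points: np.ndarray, radius: float,
                 value: float = 1.0, amplitudes: Optional[np.ndarray] = None,
                 gaussian: bool = False) -> None:
    """Paint disks (or additive Gaussian dabs) centered at float points."""
    h, w = canvas.shape
    r_int = int(np.ceil(radius if not gaussian else 3 * radius))
    span = np.arange(-r_int, r_int + 1)
    dy, dx = np.meshgrid(span, span, indexing="ij")
    dist2 = dy**2 + dx**2
    if gaussian:
        kernel = np.exp(-dist2 / (2.0 * radius**2))
    else:
        kernel = (dist2 <= radius**2).astype(float)
    for k, (pr, pc) in enumerate(points):
        r0, c0 = int(round(pr)), int(round(pc))
        rr0, rr1 = max(0, r0 - r_int), min(h, r0 + r_int + 1)
        cc0, cc1 = max(0, c0 - r_int), min(w, c0 + r_int + 1)
        if rr0 >= rr1 or cc0 >= cc1:
            continue
        kr0, kc0 = rr0 - (r0 - r_int), cc0 - (c0 - r_int)
        sub = kernel[kr0: kr0 + rr1 - rr0, kc0: kc0 + cc1 - cc0]
        amp = value if amplitudes is None else amplitudes[k]
        if gaussian:
            canvas[rr0:rr1, cc0:cc1] += amp * sub
        else:
            np.maximum(canvas[rr0:rr1, cc0:cc1], amp * sub, out=canvas[rr0:rr1, cc0:cc1])


def rasterize_vessels(vessels: Sequence[Vessel], shape: tuple[int, int]) -> np.ndarray:
    """Binary union mask of all vessels at their stated diameters."""
    mask = np.zeros(shape, dtype=float)
    for v in vessels:
        # resample at <=0.5 px spacing to avoid scalloping
        n = max(int(v.length_px * 2), 2)
        pts = v.point_at(np.linspace(0, v.length_px, n, endpoint=False))
        _paint_disks(mask, pts, radius=(v.diameter_px - 1) / 2.0)
    return mask > 0.5


def _motion_blur_kernel(length: int, angle_rad: float) -> np.ndarray:
    n = max(int(length), 1)
    k = np.zeros((2 * n + 1, 2 * n + 1))
    t = np.linspace(-(n - 1) / 2.0, (n - 1) / 2.0, max(n * 4, 2))
    rr = np.round(n + t * np.sin(angle_rad)).astype(int)
    cc = np.round(n + t * np.cos(angle_rad)).astype(int)
    k[rr, cc] = 1.0
    return k / k.sum()


def render_sequence(
    vessels: Sequence[Vessel], cfg: SceneConfig
) -> tuple[FrameSequence, GroundTruth]:
    """Render a frame sequence and its ground truth from a vessel set."""
    rng = np.random.default_rng(cfg.seed + 1)
    H, W = cfg.frame_shape
    pad = cfg.pad
    ch, cw = H + 2 * pad, W + 2 * pad

    canvas_mask = rasterize_vessels(vessels, (ch, cw))
    vessel_dark = ndimage.gaussian_filter(canvas_mask.astype(float), 0.8)

    yy, xx = np.mgrid[0:ch, 0:cw]
    gx, gy = rng.uniform(-1, 1, 2)
    illum = gx * (xx / cw - 0.5) + gy * (yy / ch - 0.5)
    illum += 0.5 * np.cos(2 * np.pi * (xx / cw) * rng.uniform(0.5, 1.5) + rng.uniform(0, 6.28))
    illum = cfg.illumination_amplitude * illum / max(np.abs(illum).max(), 1e-9)
    base = cfg.background + illum - cfg.vessel_contrast * vessel_dark

    # per-vessel cluster layout: arc phases fixed at t=0, advance with velocity
    cluster_arcs0 = []
    for v in vessels:
        n_cl = max(int(v.length_px // cfg.cluster_spacing_px), 1)
        phase = rng.uniform(0, cfg.cluster_spacing_px)
        cluster_arcs0.append(phase + np.arange(n_cl) * (v.length_px / n_cl))

    # global motion: sinusoidal drift + cumulative saccade steps
    t_s = np.arange(cfg.n_frames) / cfg.fps
    ph_x, ph_y = rng.uniform(0, 2 * np.pi, 2)
    off_x = cfg.drift_amplitude_px * np.sin(2 * np.pi * t_s / cfg.drift_period_s + ph_x)
    off_y = cfg.drift_amplitude_px * np.sin(2 * np.pi * t_s / cfg.drift_period_s + ph_y)
    for f, (sdx, sdy) in cfg.saccades.items():
        off_x[int(f):] += sdx
        off_y[int(f):] += sdy
    if not cfg.subpixel_motion:
        off_x = np.round(off_x)
        off_y = np.round(off_y)
    if np.abs(off_x).max() > pad or np.abs(off_y).max() > pad:
        raise ValueError("global motion exceeds canvas padding; vessels leave the frame")

    sigma_noise = cfg.vessel_contrast / cfg.snr if cfg.snr else 0.0
    dab_sigma = {id(v): max(v.diameter_px / 4.0, 1.0) for v in vessels}
    frames = np.empty((cfg.n_frames, H, W))
    blur_set = set(int(b) for b in cfg.blur_frames)
    blur_angles = {b: rng.uniform(0, np.pi) for b in sorted(blur_set)}
    half_len = cfg.cluster_len_px / 2.0

    for t in range(cfg.n_frames):
        cluster_dark = np.zeros((ch, cw))
        for v, arcs0 in zip(vessels, cluster_arcs0):
            speed_px_s = v.velocity_mm_s * 1000.0 / cfg.microns_per_pixel
            centers = arcs0 + speed_px_s * t_s[t]
            sig = dab_sigma[id(v)]
            # longitudinal Gaussian profile sampled every 0.5 px of arc
            offs = np.arange(-half_len, half_len + 0.25, 0.5)
            w_long = np.exp(-(offs / (half_len / 1.5)) ** 2)
            amp0 = cfg.cluster_contrast * 0.5 / (np.sqrt(2 * np.pi) * sig)
            for a0 in centers:
                pts = v.point_at(a0 + offs)
                _paint_disks(cluster_dark, pts, radius=sig,
                             amplitudes=amp0 * w_long, gaussian=True)
        scene = base - np.minimum(cluster_dark, cfg.cluster_contrast) * canvas_mask
        if cfg.subpixel_motion:
            shifted = ndimage.shift(scene, (off_y[t], off_x[t]), order=1, mode="nearest")
            frame = shifted[pad: pad + H, pad: pad + W]
        else:
            r0 = pad - int(off_y[t])
            c0 = pad - int(off_x[t])
            frame = scene[r0: r0 + H, c0: c0 + W]
        if t in blur_set:
            frame = ndimage.convolve(frame, _motion_blur_kernel(cfg.blur_len_px,
                                                                blur_angles[t]))
        if sigma_noise > 0:
            frame = frame + rng.normal(0.0, sigma_noise, frame.shape)
        frames[t] = np.clip(frame, 0.0, 1.0)

    mask = canvas_mask[pad: pad + H, pad: pad + W]
    frame_vessels = [
        Vessel(points=v.points - pad, diameter_px=v.diameter_px,
               velocity_mm_s=v.velocity_mm_s, arc=v.arc.copy())
        for v in vessels
    ]
    gt = GroundTruth(
        mask=mask,
        vessels=frame_vessels,
        displacements_px=np.stack([off_x, off_y], axis=1),
        blurred_frames=sorted(blur_set & set(range(cfg.n_frames))),
        canvas_mask=canvas_mask,
    )
    seq = FrameSequence(frames, fps=cfg.fps, microns_per_pixel=cfg.microns_per_pixel)
    return seq, gt


def generate_scene(cfg: SceneConfig) -> tuple[FrameSequence, GroundTruth]:
    """Convenience wrapper: generate vessels and render in one call."""
    rng = np.random.default_rng(cfg.seed)
    vessels = generate_vessels(cfg, rng)
    return render_sequence(vessels, cfg)
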