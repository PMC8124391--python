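"""Ground-truth-recovery experiments on synthetic scenes.

Each function runs one self-contained experiment of the pipeline against
the synthetic generator's ground truth and returns plain numbers: optical
constants recomputed from system parameters, residual displacement after
the two motion-correction steps, normalized-correlation agreement with a
brute-force scorer, velocity recovery across the physiological range,
morphology estimator exactness, and the scaled-down segmentation training
result.  Both the test suite and the acceptance script drive these.
"""

from __future__ import annotations

import numpy as np

from .correlation import ncc_map
from .morphology import (
    classify_junctions,
    extract_segments,
    segment_diameter,
    skeletonize,
)
from .optics import OpticalConfig, field_of_view_mm, microns_per_pixel, pixels_per_rbc
from .registration import register_translation, select_frames
from .synthetic import SceneConfig, generate_scene
from .template_matching import correct_sequence, select_template_vessel
from .velocimetry import build_sta, estimate_slopes, velocity_from_slopes

__all__ = [
    "optics_summary",
    "patch_plan_summary",
    "two_step_motion_experiment",
    "ncc_oracle_discrepancy",
    "velocity_recovery_experiment",
    "morphology_oracle_experiment",
    "dice_identity_experiment",
    "segmentation_training_experiment",
]

VELOCITY_GRID_MM_S = (0.08, 0.15, 0.25, 0.34)


def optics_summary() -> dict:
    """Optical constants of the real system recomputed from first principles."""
    cfg = OpticalConfig(pixel_pitch_um=3.45, magnification=3.798, fps=25.0,
                        rbc_diameter_um=7.5, frame_width_px=2208,
                        frame_height_px=1848)
    fov_w, fov_h = field_of_view_mm(cfg)
    return {
        "microns_per_pixel": microns_per_pixel(cfg),
        "pixels_per_rbc": pixels_per_rbc(cfg),
        "fov_width_mm": fov_w,
        "fov_height_mm": fov_h,
    }


def patch_plan_summary(per_image: int = 5000, n_images: int = 60,
                       val_fraction: float = 0.2) -> dict:
    """Patch counts of the full-scale training plan and their 4:1 split."""
    from .segmentation import train_val_split

    total = per_image * n_images
    tr, va = train_val_split(total, val_fraction=val_fraction, seed=0)
    return {"patches_total": total, "patches_train": len(tr),
            "patches_val": len(va)}


def two_step_motion_experiment(seed: int = 0) -> dict:
    """Residual displacement after coarse registration and template matching.

    Renders the default 70-frame scene (saccades up to ~25 px, 5 px
    sinusoidal drift, 3 blurred frames, SNR 10), runs both correction steps,
    and compares recovered against applied displacements.  Residuals are
    mean absolute displacement components over kept frames, in pixels.
    """
    cfg = SceneConfig(seed=seed)
    seq, gt = generate_scene(cfg)
    report = select_frames(seq)
    reg = register_translation(seq, report)
    truth = (gt.displacements_px[report.kept_indices]
             - gt.displacements_px[report.template_index])
    resid1 = reg.displacements - truth

    graph = segment_diameter(extract_segments(skeletonize(gt.mask)), gt.mask)
    selection = select_template_vessel(
        graph, reg.registered.frames[reg.template_position])
    fine = correct_sequence(reg.registered, selection)
    resid2 = (reg.displacements + fine.displacements) - truth
    return {
        "n_frames_kept": len(report.kept_indices),
        "n_frames_rejected": len(seq) - len(report.kept_indices),
        "step1_mean_resid_px": float(np.abs(resid1).mean()),
        "step1_max_resid_px": float(np.abs(resid1).max()),
        "step2_mean_resid_px": float(np.abs(resid2).mean()),
        "step2_max_resid_px": float(np.abs(resid2).max()),
    }


def _brute_force_ncc(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Literal per-placement normalized correlation (the independent oracle)."""
    th, tw = template.shape
    H, W = image.shape
    out = np.zeros((H - th + 1, W - tw + 1))
    tnorm = np.sqrt(np.sum(template * template))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            win = image[i:i + th, j:j + tw]
            out[i, j] = np.sum(template * win) / (tnorm * np.sqrt(np.sum(win * win)))
    return out


def ncc_oracle_discrepancy(seed: int = 0, n_instances: int = 20,
                           frame_size: int = 32, template_size: int = 8) -> float:
    """Max |difference| between ncc_map and the brute-force scorer over all
    placements of random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        frame = rng.random((frame_size, frame_size))
        tpl = rng.random((template_size, template_size))
        got = ncc_map(frame, tpl)
        want = _brute_force_ncc(frame, tpl)
        worst = max(worst, float(np.abs(got - want).max()))
    return worst


def velocity_recovery_experiment(seed: int = 0,
                                 velocities=VELOCITY_GRID_MM_S,
                                 snr: float = 10.0) -> dict:
    """Recover known flow speeds from single-vessel scenes at SNR 10.

    One 70-frame motion-free scene per ground-truth velocity; the vessel
    mask comes from the generator's ground truth so the experiment isolates
    the velocimetry chain (skeleton, STA, slope, conversion).
    """
    out = {}
    for v in velocities:
        cfg = SceneConfig(seed=seed + 100, n_vessels=1, saccades={},
                          drift_amplitude_px=0.0, blur_frames=(),
                          velocity_mm_s_range=(v, v), snr=snr)
        seq, gt = generate_scene(cfg)
        graph = segment_diameter(extract_segments(skeletonize(gt.mask)), gt.mask)
        seg = max(graph.segments, key=lambda s: s.length_px)
        sta = build_sta(seq, seg)
        est = velocity_from_slopes(estimate_slopes(sta), sta)
        rel = (abs(est.velocity_mm_s - v) / v * 100.0
               if est.velocity_mm_s is not None else float("nan"))
        out[v] = {"estimate_mm_s": est.velocity_mm_s, "rel_err_pct": rel,
                  "n_streaks": est.n_streaks}
    return out


def morphology_oracle_experiment() -> dict:
    """Exactness of the morphology estimators on analytic fixtures."""
    # diameters of drawn odd-width ribbons
    diam_err = 0.0
    for w in range(3, 16, 2):
        mask = np.zeros((31, 60), bool)
        r0 = 15 - w // 2
        mask[r0:r0 + w, 5:45] = True
        g = segment_diameter(extract_segments(skeletonize(mask)), mask)
        diam_err = max(diam_err, abs(g.segments[0].diameter_px - w))

    def n_segments(n):
        sk = np.zeros((10, 40), bool)
        sk[5, 2:2 + n] = True
        return len(extract_segments(sk).segments)

    t = np.zeros((9, 9), bool)
    t[4, 1:8] = True
    t[5:8, 4] = True
    t_bif, _ = classify_junctions(t)

    plus = np.zeros((9, 9), bool)
    plus[4, 1:8] = True
    plus[1:8, 4] = True
    _, plus_cross = classify_junctions(plus)

    return {
        "diameter_max_abs_err_px": float(diam_err),
        "segments_kept_at_15px": n_segments(15),
        "segments_kept_at_20px": n_segments(20),
        "t_center_is_bifurcation": bool([4, 4] in t_bif.tolist()),
        "plus_center_is_crossover": bool([4, 4] in plus_cross.tolist()),
    }


def dice_identity_experiment() -> dict:
    """The Dice statistic on its defining cases."""
    from .segmentation import dice_coefficient

    m = (np.random.default_rng(0).random((32, 32)) > 0.6).astype(float)
    a = np.zeros((16, 16)); a[:8] = 1
    b = np.zeros((16, 16)); b[8:] = 1
    h1 = np.zeros(20); h1[0:10] = 1
    h2 = np.zeros(20); h2[5:15] = 1
    return {
        "dice_identical": dice_coefficient(m, m),
        "dice_disjoint": dice_coefficient(a, b),
        "dice_half_overlap": dice_coefficient(h1, h2),
    }


def segmentation_training_experiment(seed: int = 0, n_patches: int = 2000,
                                     epochs: int = 20) -> dict:
    """Scaled-down synthetic training run; held-out full-image Dice."""
    from .segmentation import scaled_down_training_run

    model, history, heldout = scaled_down_training_run(
        n_patches=n_patches, epochs=epochs, seed=seed)
    return {
        "final_val_dice": history["val_dice"][-1],
        "best_val_dice": max(history["val_dice"]),
        "heldout_dice": heldout,
        "n_patches": n_patches,
        "epochs": epochs,
    }
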