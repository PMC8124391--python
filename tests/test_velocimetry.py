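"""Observability ranking, STA construction, slope and velocity estimation."""

import numpy as np
import pytest

from conjuflow.morphology import VesselSegment, VesselGraph, extract_segments, segment_diameter, skeletonize
from conjuflow.velocimetry import (
    STAImage,
    VelocityEstimate,
    build_sta,
    estimate_slopes,
    measure_velocities,
    observability_rank,
    velocity_from_slopes,
)

from conftest import make_sequence


def _line_segment(row, c0, c1, sid=1):
    return VesselSegment(id=sid, pixels=np.array([[row, c] for c in range(c0, c1)]),
                         length_px=float(c1 - c0))


def _synthetic_sta(slope, n_rows=120, n_cols=70, offsets=(20,), noise=0.0,
                   seed=0, row_scale=1.0, fps=25.0):
    """STA with ideal dark streaks of a given slope on a bright background."""
    rng = np.random.default_rng(seed)
    m = np.full((n_rows, n_cols), 0.8)
    for t in range(n_cols):
        for off in offsets:
            r = off + slope * t
            rr = np.arange(n_rows)
            m[:, t] -= 0.4 * np.exp(-((rr - r) / 2.0) ** 2)
    if noise:
        m += rng.normal(0, noise, m.shape)
    return STAImage(matrix=m, row_scale_um=row_scale, col_scale_s=1.0 / fps,
                    segment_id=1)


class TestObservabilityRank:
    def test_flowing_vessel_outranks_static(self, still_scene):
        cfg, seq, gt = still_scene
        g = segment_diameter(extract_segments(skeletonize(gt.mask)), gt.mask)
        static = seq.frames.mean(axis=0)[None].repeat(len(seq), axis=0)
        static_seq = make_sequence(static)
        # same graph: on a static sequence all sigma_t collapse to ~0
        live = observability_rank(seq, g)
        froz = observability_rank(static_seq, g)
        assert live.sigma_t.max() > 100 * froz.sigma_t.max()

    def test_alpha_zero_is_pure_length_ordering(self):
        rng = np.random.default_rng(0)
        frames = rng.random((5, 40, 80))
        seq = make_sequence(frames)
        segs = [_line_segment(10, 5, 75, sid=1), _line_segment(20, 5, 30, sid=2),
                _line_segment(30, 5, 55, sid=3)]
        rank = observability_rank(seq, VesselGraph(segs), alpha=0.0, beta=1.0, k=3)
        assert rank.selected_ids == [1, 3, 2]

    def test_top_k_limits_selection(self):
        rng = np.random.default_rng(1)
        seq = make_sequence(rng.random((4, 30, 90)))
        segs = [_line_segment(5 + 3 * i, 2, 20 + 8 * i, sid=i + 1) for i in range(6)]
        rank = observability_rank(seq, VesselGraph(segs), k=2)
        assert len(rank.selected_ids) == 2

    def test_single_frame_rejected(self):
        seq = make_sequence(np.random.default_rng(0).random((1, 30, 30)))
        with pytest.raises(ValueError):
            observability_rank(seq, VesselGraph([_line_segment(5, 2, 25)]))


class TestBuildSta:
    def test_shape_rows_by_frames(self):
        rng = np.random.default_rng(2)
        seq = make_sequence(rng.random((70, 40, 320)))
        seg = _line_segment(20, 5, 305)  # 300 px
        sta = build_sta(seq, seg)
        assert sta.matrix.shape == (300, 70)

    def test_static_scene_columns_identical(self):
        frame = np.random.default_rng(3).random((30, 60))
        seq = make_sequence(np.stack([frame] * 8))
        sta = build_sta(seq, _line_segment(10, 5, 50))
        assert np.allclose(sta.matrix, sta.matrix[:, :1])

    def test_moving_blob_advances_two_rows_per_column(self):
        n_frames, length = 12, 60
        frames = np.full((n_frames, 20, 80), 0.9)
        for t in range(n_frames):
            c = 10 + 2 * t  # blob at column 10 + 2t on row 8
            frames[t, 8, c] = 0.0
        seq = make_sequence(frames)
        sta = build_sta(seq, _line_segment(8, 5, 75))
        mins = np.argmin(sta.matrix, axis=0)
        assert np.all(np.diff(mins) == 2)

    def test_row_scale_accounts_for_diagonal_steps(self):
        # a 45-degree chain advances sqrt(2) px of arc per row
        pix = np.array([[i, i] for i in range(40)])
        seg = VesselSegment(id=1, pixels=pix, length_px=40.0)
        seq = make_sequence(np.random.default_rng(0).random((3, 50, 50)))
        sta = build_sta(seq, seg)
        assert sta.row_scale_um == pytest.approx(
            np.sqrt(2) * seq.microns_per_pixel, rel=1e-6)

    def test_out_of_bounds_centerline_raises(self):
        seq = make_sequence(np.zeros((3, 20, 20)) + 0.5)
        with pytest.raises(ValueError):
            build_sta(seq, _line_segment(10, 5, 30))

    def test_true_frame_times_preserved(self):
        frames = np.random.default_rng(1).random((5, 20, 40))
        seq = make_sequence(frames)
        sub = seq.subset([0, 1, 3, 4])  # frame 2 rejected upstream
        sta = build_sta(sub, _line_segment(10, 5, 35))
        np.testing.assert_array_equal(sta.col_positions, [0, 1, 3, 4])


class TestEstimateSlopes:
    def test_single_ideal_streak(self):
        sta = _synthetic_sta(2.0, offsets=(10,))
        est = estimate_slopes(sta)
        assert len(est.slopes_px_per_frame) >= 1
        assert est.slopes_px_per_frame[0] == pytest.approx(2.0, abs=0.05)

    def test_pure_noise_yields_empty(self):
        rng = np.random.default_rng(0)
        sta = STAImage(matrix=rng.normal(0.5, 0.05, (100, 60)),
                       row_scale_um=1.0, col_scale_s=0.04, segment_id=1)
        est = estimate_slopes(sta)
        assert est.slopes_px_per_frame == []
        assert est.n_streaks == 0

    def test_two_parallel_streaks_both_found(self):
        sta = _synthetic_sta(1.5, offsets=(15, 55), noise=0.01)
        est = estimate_slopes(sta)
        assert est.n_streaks == 2
        for m in est.slopes_px_per_frame:
            assert m == pytest.approx(1.5, abs=0.05)

    def test_steep_slope_resolved(self):
        sta = _synthetic_sta(13.0, n_rows=400, offsets=(10, 150, 290), noise=0.01)
        est = estimate_slopes(sta)
        assert est.slopes_px_per_frame[0] == pytest.approx(13.0, rel=0.03)


def test_manual_endpoint_slopes():
    from conjuflow.velocimetry import slopes_from_endpoints
    est = slopes_from_endpoints([((10, 0), (50, 20)), ((0, 5), (30, 20))])
    assert est.slopes_px_per_frame == pytest.approx([2.0, 2.0])
    assert est.n_streaks == 2
    with pytest.raises(ValueError):
        slopes_from_endpoints([((0, 3), (5, 3))])


def test_subpixel_peak_refinement():
    from scipy import ndimage as ndi
    from conjuflow.template_matching import match_template
    rng = np.random.default_rng(0)
    big = ndi.gaussian_filter(rng.random((80, 90)), 2)
    # frame shifted by half a pixel: subpixel estimate lands between 0 and 1
    frame = ndi.shift(big, (0.5, 0.0), order=3)[20:70, 20:70]
    tpl = big[30:50, 30:55]
    dx, dy, _ = match_template(frame, tpl, ref_pos=(10, 10), subpixel=True)
    assert isinstance(dx, float)
    assert -1.0 < dy - (-0.5) < 1.0  # near the true half-pixel offset


class TestVelocityFromSlopes:
    def test_hand_conversion(self):
        sta = _synthetic_sta(2.0, row_scale=0.90837, fps=25.0)
        est = VelocityEstimate([2.0], None, 1, 10.0)
        est = velocity_from_slopes(est, sta)
        assert est.velocity_mm_s == pytest.approx(2 * 0.90837 * 25 / 1000, rel=1e-9)

    def test_zero_slope_zero_velocity(self):
        sta = _synthetic_sta(0.5)
        est = velocity_from_slopes(VelocityEstimate([0.0], None, 1, 5.0), sta)
        assert est.velocity_mm_s == 0.0

    def test_empty_slopes_missing_velocity(self):
        sta = _synthetic_sta(0.5)
        est = velocity_from_slopes(VelocityEstimate([], None, 0, 0.0), sta)
        assert est.velocity_mm_s is None


class TestEndToEnd:
    def test_known_velocity_recovered_within_ten_percent(self):
        from conjuflow.synthetic import SceneConfig, generate_scene
        v = 0.2
        cfg = SceneConfig(seed=21, n_vessels=1, saccades={}, drift_amplitude_px=0.0,
                          blur_frames=(), velocity_mm_s_range=(v, v), snr=10.0)
        seq, gt = generate_scene(cfg)
        g = segment_diameter(extract_segments(skeletonize(gt.mask)), gt.mask)
        seg = max(g.segments, key=lambda s: s.length_px)
        sta = build_sta(seq, seg)
        est = velocity_from_slopes(estimate_slopes(sta), sta)
        assert est.velocity_mm_s == pytest.approx(v, rel=0.10)

    def test_velocity_invariant_to_intensity_scaling(self):
        sta = _synthetic_sta(3.0, offsets=(20, 60), noise=0.005)
        est1 = velocity_from_slopes(estimate_slopes(sta), sta)
        sta2 = STAImage(matrix=sta.matrix * 0.37, row_scale_um=sta.row_scale_um,
                        col_scale_s=sta.col_scale_s, segment_id=1)
        est2 = velocity_from_slopes(estimate_slopes(sta2), sta2)
        assert est1.velocity_mm_s == pytest.approx(est2.velocity_mm_s, rel=1e-6)

    def test_fps_doubling_invariance(self):
        # doubling fps while halving per-frame displacement: same velocity
        sta_a = _synthetic_sta(2.0, fps=25.0, noise=0.005)
        sta_b = _synthetic_sta(1.0, fps=50.0, noise=0.005)
        va = velocity_from_slopes(estimate_slopes(sta_a), sta_a).velocity_mm_s
        vb = velocity_from_slopes(estimate_slopes(sta_b), sta_b).velocity_mm_s
        assert va == pytest.approx(vb, rel=0.02)

    def test_measure_velocities_table(self, still_scene):
        cfg, seq, gt = still_scene
        table, stas = measure_velocities(seq, gt.mask, k=15)
        assert {"vessel_id", "diameter_um", "length_mm", "velocity_mm_s"} <= set(table.columns)
        assert len(table) >= 1
        measured = table["velocity_mm_s"].dropna()
        assert len(measured) >= 1
        # all measured speeds fall in the configured physiological range, loosely
        assert measured.between(0.02, 0.6).all()
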