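"""Geometric indicators: circle fit, spine ratios, head and leg values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bovigait.indicators import (
    CHANNELS,
    IndicatorConfig,
    angle_ratio_from_points,
    compute_indicator_series,
    distance_ratio_from_points,
    fit_circle,
    head_position_norm,
    leg_pair_distance,
    spine_distance_ratio,
)
from bovigait.skeleton_io import SKELETON, FrameObservation, canonicalize
from bovigait.synthetic_gait import GaitParams, simulate_passage


def _circle_points(center, radius, angles_deg):
    a = np.deg2rad(np.asarray(angles_deg, float))
    return np.column_stack([center[0] + radius * np.cos(a), center[1] + radius * np.sin(a)])


class TestFitCircle:
    def test_circumcircle_of_three_points(self):
        fit = fit_circle([(0, 0), (2, 0), (1, 1)])
        np.testing.assert_allclose(fit.center, (1, 0), atol=1e-12)
        np.testing.assert_allclose(fit.radius, 1.0, atol=1e-12)
        assert not fit.degenerate

    def test_exact_five_point_recovery(self):
        pts = _circle_points((3, -2), 5.0, [10, 60, 90, 120, 170])
        fit = fit_circle(pts)
        np.testing.assert_allclose(fit.center, (3, -2), atol=1e-6)
        np.testing.assert_allclose(fit.radius, 5.0, atol=1e-6)
        assert fit.rms_residual < 1e-9

    @pytest.mark.parametrize("radius", [0.1, 1.0, 37.0, 1e2, 1e4])
    def test_radius_range_oracle(self, radius, rng):
        center = rng.uniform(-100, 100, 2)
        angles = np.sort(rng.uniform(0, 140, 6))
        fit = fit_circle(_circle_points(center, radius, angles))
        np.testing.assert_allclose(fit.center, center, atol=1e-6 * max(1, radius))
        np.testing.assert_allclose(fit.radius, radius, rtol=1e-6)

    def test_collinear_is_degenerate(self):
        fit = fit_circle([(0, 0), (1, 0), (2, 0), (3, 0)])
        assert fit.degenerate

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_circle([(0, 0), (1, 1)])
        with pytest.raises(ValueError, match="coincident"):
            fit_circle([(2, 2)] * 5)


class TestSpineAngleRatio:
    def test_collinear_spine_is_one(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        assert angle_ratio_from_points(pts) == pytest.approx(1.0, abs=1e-12)

    def test_right_angle_raw_fallback(self):
        # Neck (0,0), Spine_2 (1,1), Spine_4 (2,0): 90 degrees at the vertex
        pts = np.array([[0, 0], [0.5, 0.5], [1, 1], [1.5, 0.5], [2, 0.0]])
        assert angle_ratio_from_points(pts, angle_mode="raw") == pytest.approx(0.5, abs=1e-12)

    def test_inscribed_angle_on_unit_circle(self):
        # arc Neck..Spine_4 spans 160 deg, so the angle at Spine_2 is
        # (360 - 160)/2 = 100 deg -> ratio 0.5556
        pts = _circle_points((0, 0), 1.0, [170, 120, 90, 60, 10])
        assert angle_ratio_from_points(pts) == pytest.approx(100.0 / 180.0, abs=1e-6)
        # direct vector arithmetic agrees (points already on the circle)
        assert angle_ratio_from_points(pts, "raw") == pytest.approx(100.0 / 180.0, abs=1e-6)


class TestSpineDistanceRatio:
    def test_equally_spaced_collinear_is_one(self):
        pts = np.column_stack([np.arange(5.0) * 2.0, np.full(5, 3.0)])
        assert distance_ratio_from_points(pts) == pytest.approx(1.0, abs=1e-12)

    def test_worked_chain(self):
        pts = np.array([[0, 0], [1, 1], [2, 1.3], [3, 1], [4, 0.0]])
        assert distance_ratio_from_points(pts) == pytest.approx(0.813588, abs=1e-6)

    @given(scale=st.floats(0.1, 1e3), dx=st.floats(-1e3, 1e3), dy=st.floats(-1e3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_similarity_invariance(self, scale, dx, dy):
        pts = np.array([[0, 0], [1, 1], [2, 1.3], [3, 1], [4, 0.0]])
        moved = pts * scale + [dx, dy]
        assert distance_ratio_from_points(moved) == pytest.approx(
            distance_ratio_from_points(pts), abs=1e-9
        )


def _frame(keypoints, visible=None, bbox=None):
    kps = np.asarray(keypoints, float)
    if bbox is None:
        bbox = [kps[:, 0].min() - 5, kps[:, 1].min() - 5,
                kps[:, 0].max() + 5, kps[:, 1].max() + 5]
    vis = np.ones(22, bool) if visible is None else visible
    return FrameObservation(frame_index=0, bbox=bbox, keypoints=kps, visible=vis)


def _base_keypoints():
    """A plausible canonical-frame cow: hooves at y=0, spine at y=2."""
    kps = np.zeros((22, 2))
    for i, name in enumerate(SKELETON.names):
        kps[i] = [i * 0.3, 1.0]
    for j, name in enumerate(SKELETON.groups["spine"]):
        kps[SKELETON.index(name)] = [4.0 - j, 2.0]
    for hoof in SKELETON.hoof_set:
        kps[SKELETON.index(hoof), 1] = 0.0
    kps[SKELETON.index("Eye")] = [4.5, 1.5]
    return kps


class TestHeadAndLegs:
    def test_head_norm_levels(self):
        kps = _base_keypoints()
        f = _frame(kps)
        # eye at 1.5 between ground 0 and back 2.0
        assert head_position_norm(f) == pytest.approx(0.75, abs=1e-12)
        kps2 = kps.copy()
        kps2[SKELETON.index("Eye"), 1] = 0.0
        assert head_position_norm(_frame(kps2)) == pytest.approx(0.0, abs=1e-12)
        kps3 = kps.copy()
        kps3[SKELETON.index("Eye"), 1] = 2.0
        assert head_position_norm(_frame(kps3)) == pytest.approx(1.0, abs=1e-12)

    def test_head_invalid_when_back_not_above_ground(self):
        kps = _base_keypoints()
        for name in SKELETON.groups["spine"]:
            kps[SKELETON.index(name), 1] = -1.0
        assert np.isnan(head_position_norm(_frame(kps)))

    def test_leg_distance_arithmetic(self):
        kps = _base_keypoints()
        kps[SKELETON.index("FR_Hoof"), 0] = 3.0
        kps[SKELETON.index("BR_Hoof"), 0] = 2.4
        f = _frame(kps)
        assert leg_pair_distance(f, "FR_BR") == pytest.approx(0.3, abs=1e-12)
        kps[SKELETON.index("BR_Hoof"), 0] = 3.0
        assert leg_pair_distance(_frame(kps), "FR_BR") == pytest.approx(0.0, abs=1e-12)

    def test_leg_distance_similarity_invariance(self):
        kps = _base_keypoints()
        kps[SKELETON.index("FR_Hoof"), 0] = 3.1
        f1 = _frame(kps)
        f2 = _frame(kps * 17.0 + [3.0, -11.0])
        assert leg_pair_distance(f2, "FR_BR") == pytest.approx(
            leg_pair_distance(f1, "FR_BR"), abs=1e-9
        )


class TestIndicatorSeries:
    def test_grade1_spine_near_straight(self):
        track, _ = simulate_passage(GaitParams(grade=1, seed=21, noise_sigma=0.0))
        series = compute_indicator_series(canonicalize(track))
        vals = series.values["spine_distance_ratio"]
        assert np.nanmin(vals) >= 0.999
        assert np.nanmean(vals) >= 0.995

    def test_series_lengths_match_frames(self):
        track, _ = simulate_passage(GaitParams(grade=3, seed=22, n_cycles=2))
        series = compute_indicator_series(canonicalize(track))
        for name in CHANNELS:
            assert series.values[name].size == track.n_frames
            assert series.valid[name].size == track.n_frames

    def test_invalid_frames_are_flagged_not_zero(self):
        track, _ = simulate_passage(GaitParams(grade=1, seed=23, n_cycles=2))
        series = compute_indicator_series(canonicalize(track))
        for name in CHANNELS:
            invalid = ~series.valid[name]
            if invalid.any():
                assert np.isnan(series.values[name][invalid]).all()

    def test_requires_canonical_track(self):
        track, _ = simulate_passage(GaitParams(grade=1, seed=24, n_cycles=2))
        with pytest.raises(ValueError, match="canonicalized"):
            compute_indicator_series(track)

    def test_all_swing_track_gates_head_and_legs_closed(self):
        # hooves that never slow down -> no steps -> head/leg channels invalid
        track, _ = simulate_passage(GaitParams(grade=1, seed=25, n_cycles=2,
                                               noise_sigma=0.0))
        t = canonicalize(track)
        for hoof in SKELETON.hoof_set:
            k = SKELETON.index(hoof)
            t.keypoints[:, k, 0] = 100.0 + 9.0 * np.arange(t.n_frames)
        series = compute_indicator_series(t)
        assert not series.valid["head_norm"].any()
        assert not series.valid["leg_dist_FR_BR"].any()
        assert series.n_steps == 0

    def test_monotone_in_sagitta(self):
        """Both spine ratios strictly decrease over a 10-point arch grid."""
        from bovigait.aggregation import aggregate_spine

        values = []
        for i, sag in enumerate(np.linspace(0.0, 0.18, 10)):
            track, _ = simulate_passage(
                GaitParams(grade=1, seed=26, noise_sigma=0.0, arch_sagitta=float(sag),
                           n_cycles=2)
            )
            series = compute_indicator_series(canonicalize(track))
            values.append(
                (np.nanmean(series.values["spine_angle_ratio"]),
                 np.nanmean(series.values["spine_distance_ratio"]),
                 aggregate_spine(series))
            )
        arr = np.array(values)
        assert np.all(np.diff(arr[:, 0]) < 0)
        assert np.all(np.diff(arr[:, 1]) < 0)
        assert np.all(np.diff(arr[:, 2]) < 0)


def test_indicators_invariant_to_translation_and_scale():
    track, _ = simulate_passage(GaitParams(grade=6, seed=27, n_cycles=2))
    base = compute_indicator_series(canonicalize(track))
    moved = canonicalize(track)
    moved.keypoints = moved.keypoints * 2.5 + np.array([310.0, -40.0])
    moved.bbox = np.column_stack([
        moved.bbox[:, 0] * 2.5 + 310.0, moved.bbox[:, 1] * 2.5 - 40.0,
        moved.bbox[:, 2] * 2.5 + 310.0, moved.bbox[:, 3] * 2.5 - 40.0,
    ])
    other = compute_indicator_series(moved)
    for name in CHANNELS:
        ok = base.valid[name] & other.valid[name]
        assert (base.valid[name] == other.valid[name]).all()
        np.testing.assert_allclose(
            other.values[name][ok], base.values[name][ok], atol=1e-9
        )


def test_spine_distance_ratio_never_exceeds_one(rng):
    for _ in range(50):
        pts = rng.normal(size=(5, 2))
        r = distance_ratio_from_points(pts)
        assert r <= 1.0 + 1e-12
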