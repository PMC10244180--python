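"""Keypoint I/O, kinematic channels, walking classifier, wavelet features."""

import numpy as np
import pytest

from ovipost.features import (
    FEATURE_COLUMNS,
    KeypointTrack,
    a5_center_frequencies,
    band_frequencies,
    build_feature_matrix,
    kinematic_features,
    morlet_band_features,
    morlet_magnitude,
    moving_average,
    read_keypoints,
    walking_bouts,
    write_keypoints,
    zscore,
)
from ovipost.simulate import KeypointSimParams, simulate_keypoints
from conftest import make_ethogram, set_active
from ovipost.ethogram import Ethogram


def static_track(n=100, fps=20.0, **overrides):
    """All required bodyparts at rest, full confidence."""
    from ovipost.simulate import _SKELETON

    points = {}
    for name, (x, y) in _SKELETON.items():
        arr = np.column_stack([np.full(n, x), np.full(n, y), np.full(n, 0.99)])
        points[name] = arr
    for name, arr in overrides.items():
        points[name] = arr
    return KeypointTrack(points=points, fps=fps, px_per_mm=20.0)


class TestKeypointIO:
    def test_small_fixture_roundtrip(self, tmp_path):
        n = 5
        pts = {
            "scutellum": np.column_stack([np.arange(n), np.zeros(n), np.ones(n)]),
            "ocellus": np.column_stack([np.zeros(n), np.arange(n), np.ones(n)]),
        }
        track = KeypointTrack(points=pts, fps=20.0, px_per_mm=10.0)
        p = write_keypoints(track, tmp_path / "kp.csv")
        back = read_keypoints(p, px_per_mm=10.0, fps=20.0, min_confidence=0.5)
        assert back.n_frames == 5
        for name in pts:
            assert np.allclose(back.points[name], track.points[name])

    def test_low_confidence_frame_interpolated_to_midpoint(self, tmp_path):
        arr = np.array([[0.0, 0.0, 1.0], [5.0, 9.0, 0.1], [2.0, 2.0, 1.0]])
        track = KeypointTrack(points={"scutellum": arr.copy()})
        p = write_keypoints(track, tmp_path / "kp.csv")
        back = read_keypoints(p, min_confidence=0.9)
        assert np.allclose(back.points["scutellum"][1, :2], [1.0, 1.0])
        assert back.interpolated["scutellum"] == [(1, 2)]

    def test_leading_gap_held_at_nearest_valid(self, tmp_path):
        arr = np.array([[9.0, 9.0, 0.1], [1.0, 2.0, 1.0], [1.0, 2.0, 1.0]])
        p = write_keypoints(KeypointTrack(points={"scutellum": arr}), tmp_path / "kp.csv")
        back = read_keypoints(p, min_confidence=0.9)
        assert np.allclose(back.points["scutellum"][0, :2], [1.0, 2.0])

    def test_roundtrip_on_simulated_track(self, tmp_path):
        e, _ = make_ethogram(80)
        set_active(e.activity, "walk", 10, 50)
        track, _, _ = simulate_keypoints(Ethogram(activity=e.activity), seed=4)
        p = write_keypoints(track, tmp_path / "kp.csv")
        back = read_keypoints(p, min_confidence=0.0)
        for name in track.points:
            assert np.allclose(back.points[name], track.points[name])

    def test_malformed_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError):
            read_keypoints(p)


class TestKinematics:
    def test_stationary_track_has_zero_motion_channels(self):
        kin = kinematic_features(static_track(), speed_lag_frames=10)
        for ch in ("vel", "pe", "T1", "T2", "T3", "A5_move"):
            assert np.allclose(kin[ch], 0.0)
        assert np.allclose(kin["ba"], 0.0)  # constant angle z-scores to zero

    def test_speed_from_lagged_displacement(self):
        # scutellum advances 2 px/frame; 20 px over the 0.5-s lag = 40 px/s
        n = 100
        arr = np.column_stack([2.0 * np.arange(n), np.zeros(n), np.ones(n)])
        kin = kinematic_features(static_track(n, scutellum=arr), speed_lag_frames=10)
        assert np.allclose(kin["vel"][10:], 40.0)

    def test_monotone_abdomen_rotation_gives_one_signed_velba(self):
        n = 200
        theta = np.linspace(0, 0.8, n)
        base = static_track(n)
        pivot = base.points["stripe_A2"][0, :2]
        pts = dict(base.points)
        for name in ("stripe_A5", "stripe_A6"):
            rel = pts[name][0, :2] - pivot
            x = pivot[0] + rel[0] * np.cos(theta) - rel[1] * np.sin(theta)
            y = pivot[1] + rel[0] * np.sin(theta) + rel[1] * np.cos(theta)
            pts[name] = np.column_stack([x, y, np.ones(n)])
        kin = kinematic_features(KeypointTrack(points=pts, fps=20.0), speed_lag_frames=10)
        # a monotone rotation gives a strictly one-signed angular velocity
        # (before z-scoring) and a monotone ba channel
        dba = np.diff(kin["ba"])
        assert np.all(dba > 0) or np.all(dba < 0)
        raw_velba = kin["velba"][1:]  # frame 0 is the zero-padded seed
        assert np.allclose(raw_velba, raw_velba[0])  # constant-rate ramp

    def test_vel_invariant_under_global_translation(self):
        rng = np.random.default_rng(5)
        base = static_track(60)
        jit = {k: v + np.column_stack([rng.normal(0, 1, (60, 2)), np.zeros(60)])
               for k, v in base.points.items()}
        shift = np.array([37.0, -12.0, 0.0])
        moved = {k: v + shift for k, v in jit.items()}
        k1 = kinematic_features(KeypointTrack(points=jit, fps=20.0))
        k2 = kinematic_features(KeypointTrack(points=moved, fps=20.0))
        assert np.allclose(k1["vel"], k2["vel"])

    def test_ba_invariant_under_global_rotation(self):
        rng = np.random.default_rng(6)
        base = static_track(60)
        jit = {k: v + np.column_stack([rng.normal(0, 1, (60, 2)), np.zeros(60)])
               for k, v in base.points.items()}
        c, s = np.cos(0.7), np.sin(0.7)
        rot = {}
        for k, v in jit.items():
            x, y = v[:, 0], v[:, 1]
            rot[k] = np.column_stack([c * x - s * y, s * x + c * y, v[:, 2]])
        k1 = kinematic_features(KeypointTrack(points=jit, fps=20.0))
        k2 = kinematic_features(KeypointTrack(points=rot, fps=20.0))
        assert np.allclose(k1["ba"], k2["ba"], atol=1e-8)

    def test_zscore_moments(self):
        rng = np.random.default_rng(7)
        z = zscore(rng.normal(3, 2, 1000))
        assert abs(z.mean()) < 1e-8
        assert abs(z.std() - 1) < 1e-8

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            kinematic_features(static_track(8), speed_lag_frames=10)


class TestWalkingClassifier:
    def test_constant_above_threshold_walks_everywhere(self):
        walk, bouts = walking_bouts(np.full(200, 0.30), fps=20.0)
        assert walk.all()
        assert bouts == [(0, 200)]

    def test_constant_below_threshold_never_walks(self):
        walk, bouts = walking_bouts(np.full(200, 0.28), fps=20.0)
        assert not walk.any()
        assert bouts == []

    def test_step_onset_within_half_smoothing_window(self):
        # 0 -> 1 mm/s step at frame 200: the 1-s moving average crosses
        # 0.29 within 10 frames (half the 20-frame window) of the step
        v = np.zeros(400)
        v[200:] = 1.0
        walk, bouts = walking_bouts(v, fps=20.0)
        onset = bouts[0][0]
        assert abs(onset - 200) <= 10

    def test_agrees_with_naive_sliding_window_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(5, 300))
            v = rng.gamma(1.0, 0.4, n)
            window = int(rng.integers(1, 41))
            got = moving_average(v, window)
            half = window // 2
            want = np.array([
                v[max(0, i - half): min(n, i + half + 1)].mean() for i in range(n)
            ])
            assert np.allclose(got, want)

    def test_nonpositive_smoothing_rejected(self):
        with pytest.raises(ValueError):
            walking_bouts(np.ones(10), smooth_s=0.0)


class TestWavelets:
    def test_tone_in_low_band_dominates_low_band(self):
        fps, dur = 20.0, 40.0
        t = np.arange(0, dur, 1 / fps)
        sig = np.sin(2 * np.pi * 1.0 * t)
        bands = morlet_band_features(sig, fps)
        interior = slice(int(8 * fps), int((dur - 8) * fps))
        assert np.all(bands[0, interior] > bands[1, interior])

    def test_tone_in_high_band_dominates_high_band(self):
        fps, dur = 20.0, 40.0
        t = np.arange(0, dur, 1 / fps)
        sig = np.sin(2 * np.pi * 1.8 * t)
        bands = morlet_band_features(sig, fps)
        interior = slice(int(8 * fps), int((dur - 8) * fps))
        assert np.all(bands[1, interior] > bands[0, interior])

    def test_constant_signal_has_near_zero_magnitude(self):
        bands = morlet_band_features(np.full(400, 7.3), fps=20.0)
        assert np.all(bands < 1e-8)
        logged = morlet_band_features(np.full(400, 7.3), fps=20.0, log_output=True)
        assert np.all(logged == np.log(1e-6))  # at the floor

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_magnitude(np.ones(100), fps=20.0, freqs=[11.0])

    def test_band_frequencies_log_spaced_within_band(self):
        f = band_frequencies(0.8, 1.3, 4)
        assert f[0] == 0.8 and f[-1] == pytest.approx(1.3)
        assert np.allclose(np.diff(np.log(f)), np.diff(np.log(f))[0])


class TestFeatureMatrix:
    def test_matrix_has_the_seventeen_named_columns(self):
        fm = build_feature_matrix(static_track(300), ovi_intensity=np.full(300, 100.0))
        assert tuple(fm.data.columns) == FEATURE_COLUMNS
        assert len(FEATURE_COLUMNS) == 17
        assert not fm.ovi_fallback

    def test_stationary_track_gives_floored_matrix(self):
        fm = build_feature_matrix(static_track(300), ovi_intensity=np.full(300, 100.0))
        assert np.allclose(fm.data[["vel", "pe", "T1", "T2", "T3"]].to_numpy(), 0.0)
        assert np.allclose(fm.data[["w1ovi", "w2ovi"]].to_numpy(), 0.0, atol=1e-8)
        assert np.allclose(fm.data[[f"cwt{i}" for i in range(1, 8)]].to_numpy(), np.log(1e-6))

    def test_burrow_epoch_drives_w2ovi(self):
        # 1.5 Hz ROI oscillation during a burrowing epoch raises the
        # 1.3-2.3 Hz band over the quiet epoch
        n, fps = 1200, 20.0
        t = np.arange(n) / fps
        ovi = np.full(n, 100.0)
        epoch = slice(300, 700)
        ovi[epoch] += 40 * np.sin(2 * np.pi * 1.5 * t[epoch])
        fm = build_feature_matrix(static_track(n), ovi_intensity=ovi)
        w2 = fm.data["w2ovi"].to_numpy()
        assert w2[epoch].mean() > 5 * w2[900:].mean()

    def test_missing_bodypart_raises(self):
        track = static_track(100)
        del track.points["stripe_A5"]
        with pytest.raises(KeyError, match="stripe_A5"):
            build_feature_matrix(track, ovi_intensity=np.full(100, 1.0))

    def test_fallback_flag_without_intensity_trace(self):
        fm = build_feature_matrix(static_track(300))
        assert fm.ovi_fallback

    def test_a5_centers_span_half_to_ten_hz(self):
        f = a5_center_frequencies()
        assert f[0] == 0.5 and f[-1] == pytest.approx(10.0) and len(f) == 7
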