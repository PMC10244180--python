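"""dF/F0, distance normalization, TV event detection, integral normalization."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import lsq_linear

from ovipost.calcium import (
    DetectedEvent,
    DffTrace,
    FluorescenceRecording,
    compute_dff,
    detect_events,
    event_triggered_average,
    integrate_and_normalize,
    normalize_distances,
    postexpulsion_median_integral,
    sliding_integral,
    tv_denoise,
)
from ovipost.simulate import FluorSimParams, simulate_fluorescence


def rec(green, fps=10.0):
    g = np.atleast_2d(np.asarray(green, dtype=float))
    return FluorescenceRecording(green=g, red=np.full_like(g, 50.0), fps=fps)


class TestDff:
    def test_constant_trace_gives_zero_dff(self):
        d = compute_dff(rec(np.full(500, 100.0)))
        assert np.all(d.dff == 0.0)

    def test_plateau_of_150_over_baseline_100_gives_half(self):
        f = np.full(1000, 100.0)
        f[800:] = 150.0
        d = compute_dff(rec(f), egg_out_time=70.0)
        assert np.allclose(d.dff[0, 800:], 0.5)
        assert d.baseline_f0[0] == 100.0

    def test_transient_inside_exclusion_window_spares_baseline(self):
        f = np.full(2000, 100.0)
        f[495:510] = 400.0  # extrusion transient at ~50 s
        with_excl = compute_dff(rec(f), extrusion_events=[50.0])
        assert with_excl.baseline_f0[0] == 100.0

    def test_baseline_stops_20s_before_expulsion(self):
        f = np.full(1000, 100.0)
        f[750:] = 900.0  # ramp-up before egg out at 95 s stays out of F0
        d = compute_dff(rec(f), egg_out_time=95.0)
        assert d.baseline_f0[0] == 100.0

    def test_gain_change_leaves_dff_identical(self):
        rng = np.random.default_rng(0)
        f = 100.0 + rng.gamma(2.0, 5.0, 800)
        a = compute_dff(rec(f))
        b = compute_dff(rec(3.7 * f))
        assert np.allclose(a.dff, b.dff)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            compute_dff(rec(np.full(100, 50.0)), egg_out_time=5.0)


class TestDistances:
    def test_division_by_analia_median(self):
        d = normalize_distances(np.full(50, 100.0), np.full(50, 60.0), np.full(50, 50.0))
        assert np.allclose(d.t6_egg, 2.0)
        assert d.norm_constant == 50.0

    def test_analia_normalizes_to_median_one(self):
        rng = np.random.default_rng(1)
        analia = 50 + rng.normal(0, 1, 200)
        d = normalize_distances(analia, analia, analia)
        assert np.median(d.t6_egg) == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        a, b, c = (rng.gamma(5, 10, 100) for _ in range(3))
        d1 = normalize_distances(a, b, c)
        d2 = normalize_distances(4 * a, 4 * b, 4 * c)
        assert np.allclose(d1.t6_egg, d2.t6_egg)

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError):
            normalize_distances(np.ones(5), np.ones(5), np.zeros(5))


class TestTvDenoise:
    @staticmethod
    def _dual_oracle(y, lam):
        """Exact TV solution via its bounded-least-squares dual."""
        n = len(y)
        D = sp.diags([-np.ones(n - 1), np.ones(n - 1)], [0, 1], shape=(n - 1, n)).toarray()
        res = lsq_linear(D.T, y, bounds=(-lam, lam), tol=1e-14, max_iter=3000)
        return y - D.T @ res.x

    def test_matches_dual_oracle_on_random_traces(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(1, 40))
            y = rng.normal(0, 2, n) + np.repeat(rng.normal(0, 3, 4), n)[:n]
            lam = float(rng.uniform(0.01, 2.5))
            assert np.allclose(tv_denoise(y, lam), self._dual_oracle(y, lam), atol=1e-7)

    def test_piecewise_constant_input_keeps_level_count(self):
        # K steps in, at most K+1 distinct output levels: no spurious levels
        y = np.repeat([0.0, 1.0, 0.0, 2.0], 50)
        x = tv_denoise(y, 0.1)
        assert len(np.unique(np.round(x, 9))) <= 4

    def test_zero_lambda_is_identity(self):
        y = np.random.default_rng(4).normal(0, 1, 30)
        assert np.array_equal(tv_denoise(y, 0.0), y)

    def test_mean_is_preserved(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 100)
        assert tv_denoise(y, 0.7).mean() == pytest.approx(y.mean())


class TestDetection:
    def test_pure_noise_yields_no_events(self):
        rng = np.random.default_rng(6)
        trace = 1.0 + rng.normal(0, 0.05, 3000)
        events = detect_events(trace, fps=10.0)
        assert events == []

    def test_flat_trace_warns_and_returns_nothing(self):
        with pytest.warns(UserWarning, match="flat"):
            assert detect_events(np.full(1000, 2.0), fps=10.0) == []

    def test_five_steps_recovered_within_two_frames(self):
        rng = np.random.default_rng(7)
        fps = 10.0
        trace = 1.0 + rng.normal(0, 0.1, 3000)
        truth = [300, 800, 1400, 2000, 2600]
        for f in truth:
            trace[f : f + 30] += 1.0
        events = detect_events(trace, fps=fps)
        got = [int(round(ev.onset_s * fps)) for ev in events]
        assert len(got) == 5
        assert all(abs(a - b) <= 2 for a, b in zip(got, truth))

    def test_threshold_is_one_fifth_of_regularized_max(self):
        # bump at 0.21 x max crosses the max/5 threshold; 0.19 x does not
        base = np.zeros(3000)
        base[1000:1100] = 1.0
        for height, expected in ((0.25, 2), (0.15, 1)):
            trace = base.copy()
            trace[2000:2100] = height
            events = detect_events(trace, fps=10.0, tv_lambda=0.01, hp_cutoff=0.0001)
            assert len(events) == expected


class TestIntegrals:
    def _dff(self, arr, fps=10.0):
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        return DffTrace(dff=arr, baseline_f0=np.ones(arr.shape[0]), fps=fps)

    def test_rectangular_unit_response_integrates_to_three(self):
        fps = 10.0
        d = np.zeros(2000)
        d[1000:1031] = 1.0  # unit response over exactly [0, 3] s inclusive
        integrals = sliding_integral(d, fps)
        assert integrals[1000] == pytest.approx(3.0, abs=1e-6)

    def test_zero_dff_gives_zero_integrals(self):
        d = self._dff(np.zeros(3000))
        events = [DetectedEvent(onset_s=150.0)]
        out = integrate_and_normalize(d, events, "expulsion_context", egg_out_time=200.0)
        assert np.all(out.raw == 0.0)
        assert np.all(out.normalized == 0.0)

    def test_anchors_map_to_exactly_zero_and_one(self):
        fps = 10.0
        d = np.zeros(3000)
        d[1500:1560] = 2.0  # the session maximum
        dff = self._dff(d, fps)
        integrals = sliding_integral(d, fps)
        peak_onset = int(np.nanargmax(integrals))
        events = [
            DetectedEvent(onset_s=peak_onset / fps),  # at the 1-anchor
            DetectedEvent(onset_s=30.0),              # in the flat 0-anchor region
        ]
        out = integrate_and_normalize(dff, events, "expulsion_context", egg_out_time=250.0)
        assert out.normalized[0, 0] == 1.0
        assert out.normalized[0, 1] == 0.0

    def test_extrusion_context_uses_postexpulsion_baseline(self):
        fps = 10.0
        d = np.zeros(4000)
        d[500:560] = 1.0    # pre-expulsion activity
        d[3000:3060] = 2.0  # post-expulsion extrusion response
        dff = self._dff(d, fps)
        out = integrate_and_normalize(
            dff, [DetectedEvent(onset_s=300.0)], "extrusion_context",
            egg_out_time=100.0, exclusion_events=[300.0],
        )
        assert out.anchor0[0] == 0.0  # quiet post-expulsion frames
        assert out.normalized[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_multi_event_rois_reduced_by_mean(self):
        fps = 10.0
        d = np.zeros(3000)
        d[1500:1560] = 2.0
        dff = self._dff(d, fps)
        integrals = sliding_integral(d, fps)
        peak_onset = int(np.nanargmax(integrals))
        events = [DetectedEvent(onset_s=peak_onset / fps), DetectedEvent(onset_s=30.0)]
        out = integrate_and_normalize(dff, events, "expulsion_context", egg_out_time=250.0)
        assert out.per_roi_mean[0] == pytest.approx(0.5)

    def test_postexpulsion_median_window(self):
        d = np.zeros(3000)
        d[1100:1200] = 1.0  # active 110-120 s, inside [egg+10, egg+20]
        out = postexpulsion_median_integral(self._dff(d), egg_out_time=100.0)
        assert out[0] > 0

    def test_responsive_and_silent_events_separate(self):
        p = FluorSimParams(noise_sd=1.0, amplitude_dff=1.0)
        onsets = [60.0, 120.0, 180.0]
        recd, dists, truth = simulate_fluorescence(onsets, p=p, duration_s=300.0, seed=8)
        dff = compute_dff(recd, egg_out_time=250.0)
        resp = [DetectedEvent(onset_s=t) for t in onsets]
        silent = [DetectedEvent(onset_s=t + 25.0) for t in onsets]
        out_r = integrate_and_normalize(dff, resp, "expulsion_context", egg_out_time=250.0)
        out_s = integrate_and_normalize(dff, silent, "expulsion_context", egg_out_time=250.0)
        assert out_r.normalized.min() > out_s.normalized.max()


class TestEventTriggeredAverage:
    def _dff(self, arr, fps=10.0):
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        return DffTrace(dff=arr, baseline_f0=np.ones(arr.shape[0]), fps=fps)

    def test_single_event_mean_equals_snippet_with_zero_sem(self):
        rng = np.random.default_rng(9)
        d = self._dff(rng.normal(0, 1, 2000))
        out = event_triggered_average(d, [DetectedEvent(onset_s=100.0)])
        assert np.allclose(out["mean"], out["snippets"][0])
        assert np.allclose(out["sem"], 0.0)

    def test_mean_of_zero_and_two_traces_is_one(self):
        d = DffTrace(
            dff=np.vstack([np.zeros(1000), np.full(1000, 2.0)]),
            baseline_f0=np.ones(2), fps=10.0,
        )
        out = event_triggered_average(d, [DetectedEvent(onset_s=50.0)])
        assert np.allclose(out["mean"], 1.0)

    def test_aligned_transients_peak_at_construction_time(self):
        p = FluorSimParams(noise_sd=0.2, rise_tau_s=0.3, decay_tau_s=1.0)
        onsets = [60.0, 120.0, 180.0, 240.0]
        recd, _, _ = simulate_fluorescence(onsets, p=p, duration_s=300.0, seed=10)
        dff = compute_dff(recd)
        out = event_triggered_average(dff, [DetectedEvent(onset_s=t) for t in onsets])
        peak_t = out["times_s"][int(np.nanargmax(out["mean"]))]
        # double-exponential peak time for these taus is ~0.5 s post onset
        expect = 0.3 * 1.0 / (1.0 - 0.3) * np.log(1.0 / 0.3)
        assert abs(peak_t - expect) <= 0.2

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            event_triggered_average(self._dff(np.zeros(100)), [])
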