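"""End-to-end recovery benchmarks on synthetic cohorts.

Each function here runs one pipeline stage against its generator at the
study's standard conditions and returns the measured quantities (errors,
rates, purities) as plain floats.  The acceptance script and the acceptance
test suite both drive these, so the measurement is defined in exactly one
place.
"""

from __future__ import annotations

import numpy as np

from .agreement import confusion_counts, f1_agreement
from .behavior_map import cluster_significance, embed_features, segment_density
from .calcium import (
    DetectedEvent,
    DffTrace,
    FluorescenceRecording,
    compute_dff,
    detect_events,
    integrate_and_normalize,
    sliding_integral,
)
from .episodes import StimTrial, classify_post_expulsion, egg_output_summary
from .ethogram import LABELS, LABEL_INDEX, Ethogram
from .features import (
    a5_center_frequencies,
    morlet_band_features,
    morlet_magnitude,
    walking_bouts,
)
from .simulate import (
    EthogramSimParams,
    FluorSimParams,
    simulate_cohort,
    simulate_egg_depths,
    simulate_fluorescence,
    simulate_motif_features,
)
from .transitions import (
    StartSequence,
    estimate_transitions,
    permutation_test,
    sequences_from_ethograms,
)

_NON_EGG = tuple(lab for lab in LABELS if lab != "egg_out")


# ---------------------------------------------------------------------------
# Transition statistics
# ---------------------------------------------------------------------------

def transition_recovery(seed: int = 0, n_events: int = 200, min_row_count: int = 50) -> dict:
    """Estimate the pre-phase transition matrix from a simulated cohort.

    Compares pooled row-normalized probabilities against the generating
    matrix over rows the pre-expulsion phase actually visits (at least
    ``min_row_count`` outgoing transitions).
    """
    params = EthogramSimParams()
    ethos, truths = simulate_cohort(params, n_events=n_events, n_flies=20, seed=seed)
    seqs = sequences_from_ethograms(ethos, min_pe_spacing=0.0)
    tm = estimate_transitions(seqs, phase="pre")
    truth = truths[0].transition_matrix
    rows = tm.counts.sum(axis=1) >= min_row_count
    err = float(np.abs(tm.probs[rows] - truth[rows]).max())
    return {"max_abs_error": err, "n_events": n_events, "n_rows_compared": int(rows.sum())}


def permutation_calibration(
    seed: int = 0,
    n_datasets: int = 500,
    n_seqs: int = 30,
    seq_len: int = 100,
    n_perm: int = 999,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the permutation test under i.i.d.-label null data.

    Sequences are drawn with independent uniform labels (the six
    non-point-event behaviors), so every transition structure is chance;
    the per-cell rejection rate at ``alpha`` measures calibration.
    """
    rng = np.random.default_rng(seed)
    active = [LABEL_INDEX[lab] for lab in _NON_EGG]
    hits = total = 0
    for i in range(n_datasets):
        seqs = []
        for j in range(n_seqs):
            labs = rng.choice(_NON_EGG, size=seq_len)
            seqs.append(
                StartSequence(event_id=f"d{i}s{j}", items=[(l, k) for k, l in enumerate(labs)])
            )
        tm = estimate_transitions(seqs, phase="all")
        res = permutation_test(tm, seqs, n_perm=n_perm, seed=int(rng.integers(2**31)))
        p = res.pvals[np.ix_(active, active)]
        hits += int((p < alpha).sum())
        total += p.size
    return {"rejection_rate": hits / total, "n_tests": total, "alpha": alpha}


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def event_detector_fidelity(
    seed: int = 0,
    n_traces: int = 100,
    n_events: int = 10,
    tolerance_frames: int = 2,
    noise_sd: float = 0.2,
) -> dict:
    """Precision/recall of the distance-trace event detector.

    Each trace carries ``n_events`` step events of height 5x the noise sd;
    a detection within ``tolerance_frames`` of a true onset is a hit.
    """
    fps = 10.0
    tp = fp = fn = 0
    base_seed = np.random.SeedSequence(seed).generate_state(n_traces)
    for i in range(n_traces):
        rng = np.random.default_rng(int(base_seed[i] % (2**31)))
        onsets = (20 + np.arange(n_events) * 56 + rng.integers(0, 30, n_events)).astype(float)
        p = FluorSimParams(step_height=5 * noise_sd, distance_noise_sd=noise_sd)
        _, dists, _ = simulate_fluorescence(
            list(onsets), p=p, duration_s=20 + n_events * 56 + 40,
            seed=int(base_seed[i] % (2**31)),
        )
        got = np.array([ev.onset_s for ev in detect_events(dists["t6_egg"], fps=fps)])
        matched = np.zeros(got.size, dtype=bool)
        for t in onsets:
            ok = np.flatnonzero(~matched & (np.abs(got - t) <= tolerance_frames / fps + 1e-9))
            if ok.size:
                matched[ok[0]] = True
                tp += 1
            else:
                fn += 1
        fp += int((~matched).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {"precision": precision, "recall": recall, "n_traces": n_traces}


# ---------------------------------------------------------------------------
# dF/F0 and integral anchors
# ---------------------------------------------------------------------------

def dff_integral_anchors() -> dict:
    """Deterministic checks of dF/F0 and the 3-s integral normalization."""
    fps = 10.0
    # constant fluorescence -> identically zero dF/F0
    rec = FluorescenceRecording(
        green=np.full((1, 1000), 100.0), red=np.full((1, 1000), 50.0), fps=fps
    )
    const_dev = float(np.abs(compute_dff(rec).dff).max())

    # unit rectangular response spanning [0, 3] s -> raw integral 3.0
    d = np.zeros(2000)
    d[1000:1031] = 1.0
    rect = float(sliding_integral(d, fps)[1000])

    # expulsion-context anchors map to exactly 0 and 1
    d2 = np.zeros(3000)
    d2[1500:1560] = 2.0
    dff = DffTrace(dff=d2[None, :], baseline_f0=np.ones(1), fps=fps)
    peak_onset = int(np.nanargmax(sliding_integral(d2, fps)))
    events = [DetectedEvent(onset_s=peak_onset / fps), DetectedEvent(onset_s=30.0)]
    out = integrate_and_normalize(dff, events, "expulsion_context", egg_out_time=250.0)
    return {
        "constant_dff_max_abs": const_dev,
        "rect_integral_3s": rect,
        "normalized_at_max_anchor": float(out.normalized[0, 0]),
        "normalized_at_baseline_anchor": float(out.normalized[0, 1]),
    }


# ---------------------------------------------------------------------------
# Wavelet band selectivity
# ---------------------------------------------------------------------------

def wavelet_band_selectivity(fps: float = 64.0, duration_s: float = 60.0,
                             margin_s: float = 8.0) -> dict:
    """Pure tones at all nine band centers must win their own band.

    The two ovipositor-ROI bands are compared against each other, and the
    seven A5 center-frequency channels against each other; correctness is
    the fraction of interior frames where the argmax lands in the tone's
    band.
    """
    t = np.arange(0, duration_s, 1.0 / fps)
    interior = slice(int(margin_s * fps), int((duration_s - margin_s) * fps))
    correct = total = 0
    ovi_bands = ((0.8, 1.3), (1.3, 2.3))
    for bi, (lo, hi) in enumerate(ovi_bands):
        tone = np.sin(2 * np.pi * np.sqrt(lo * hi) * t)
        mags = morlet_band_features(tone, fps, ovi_bands)
        assign = np.argmax(mags, axis=0)[interior]
        correct += int((assign == bi).sum())
        total += assign.size
    centers = a5_center_frequencies()
    for ci, f in enumerate(centers):
        tone = np.sin(2 * np.pi * f * t)
        mags = morlet_magnitude(tone, fps, centers)
        assign = np.argmax(mags, axis=0)[interior]
        correct += int((assign == ci).sum())
        total += assign.size
    return {"fraction_correct": correct / total, "n_assignments": total}


# ---------------------------------------------------------------------------
# Walking classifier
# ---------------------------------------------------------------------------

def _naive_walk(vel: np.ndarray, fps: float, threshold: float, smooth_s: float) -> np.ndarray:
    """Brute-force reimplementation: per-frame loop over the window."""
    n = vel.size
    window = max(1, int(round(smooth_s * fps)))
    half = window // 2
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = vel[lo:hi].mean() > threshold
    return out


def walking_classifier_agreement(seed: int = 0, n_traces: int = 50) -> dict:
    """Exact agreement with the naive oracle, plus the threshold constants."""
    rng = np.random.default_rng(seed)
    fps, thr, smooth = 20.0, 0.29, 1.0
    agree = total = 0
    for _ in range(n_traces):
        n = int(rng.integers(40, 600))
        vel = rng.gamma(1.2, 0.3, n)
        vel[rng.random(n) < 0.3] += rng.uniform(0.5, 2.0)
        walk, _ = walking_bouts(vel, fps=fps, threshold=thr, smooth_s=smooth)
        agree += int((walk == _naive_walk(vel, fps, thr, smooth)).sum())
        total += n
    walk_hi, _ = walking_bouts(np.full(200, 0.30), fps=fps)
    walk_lo, _ = walking_bouts(np.full(200, 0.28), fps=fps)
    return {
        "oracle_agreement": agree / total,
        "constant_0p30_walk_fraction": float(walk_hi.mean()),
        "constant_0p28_walk_fraction": float(walk_lo.mean()),
    }


# ---------------------------------------------------------------------------
# Behavior map
# ---------------------------------------------------------------------------

def map_purity(n_motifs: int, seed: int = 0, n_frames: int = 10_000,
               subsample: int = 5_000) -> dict:
    """Cluster purity of the embed/segment pipeline against motif truth."""
    X, truth = simulate_motif_features(n_motifs, n_frames=n_frames, seed=seed + 100)
    em = embed_features(X, subsample=subsample, seed=seed)
    cm = segment_density(em, grid=512, min_occupancy=0.01)
    total = correct = 0
    for k in np.unique(cm.labels):
        if k == 0:
            continue
        members = truth[cm.labels == k]
        total += members.size
        correct += int(np.bincount(members).max())
    return {"purity": correct / total, "n_clusters": cm.n_clusters, "n_frames": n_frames}


def significance_null_calibration(
    seed: int = 0, n_replicates: int = 150, n_events: int = 40,
    event_len: int = 600, n_shift: int = 199, alpha: float = 0.05,
) -> dict:
    """Rejection rate of the circular-shift cluster test on unlocked labels."""
    rng = np.random.default_rng(seed)
    hits = total = 0
    for _ in range(n_replicates):
        labels = [rng.integers(1, 4, size=event_len).astype(np.int64) for _ in range(n_events)]
        df = cluster_significance(
            labels, [event_len // 2] * n_events, fps=10.0, n_shift=n_shift,
            seed=int(rng.integers(2**31)),
        )
        hits += int((df["p"] < alpha).sum())
        total += len(df)
    rate = hits / total
    return {
        "rejection_rate": rate,
        "n_tests": total,
        "se": float(np.sqrt(alpha * (1 - alpha) / total)),
    }


# ---------------------------------------------------------------------------
# F1 agreement oracle
# ---------------------------------------------------------------------------

def f1_oracle_agreement(seed: int = 0, n_pairs: int = 100) -> dict:
    """Max |module F1 - brute-force frame-loop F1| over random pairs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        n = int(rng.integers(5, 150))
        acts = []
        for _ in range(2):
            a = rng.random((n, len(LABELS))) < 0.3
            a[:, LABEL_INDEX["walk"]] &= ~a[:, LABEL_INDEX["burrow"]]
            acts.append(a)
        a, b = Ethogram(activity=acts[0]), Ethogram(activity=acts[1])
        rep = f1_agreement(confusion_counts(a, b))
        for lab in LABELS:
            tp = fp = fn = 0
            for f in range(n):
                x = bool(acts[0][f, LABEL_INDEX[lab]])
                y = bool(acts[1][f, LABEL_INDEX[lab]])
                tp += x and y
                fp += (not x) and y
                fn += x and (not y)
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * p * r / (p + r) if p + r else 0.0
            worst = max(worst, abs(rep.f1[lab] - f1))
    return {"max_abs_f1_difference": worst, "n_pairs": n_pairs}


# ---------------------------------------------------------------------------
# Photostimulation outcome classifier
# ---------------------------------------------------------------------------

def _opto_trial(extra_burrows, n_s=220.0, fps=20.0):
    n = int(n_s * fps)
    act = np.zeros((n, len(LABELS)), dtype=bool)
    act[100:200, LABEL_INDEX["burrow"]] = True
    act[200, LABEL_INDEX["egg_out"]] = True
    for start_s, dur_s in extra_burrows:
        s = 200 + int(start_s * fps)
        act[s : s + int(dur_s * fps), LABEL_INDEX["burrow"]] = True
    return Ethogram(activity=act, egg_out_frame=200, fps=fps)


def opto_classifier_fidelity() -> dict:
    """The deterministic advance/revert rule on 20 hand-scored trials.

    Ten post-expulsion burrowing layouts (quiet, inside-gap, outside-gap,
    chained episodes) each paired with an early and a late expulsion time
    relative to the light pulses, covering both the 65-s reset rule and the
    4-s expelled-after-stimulation window.
    """
    layouts = [
        ((), "advance"),
        (((70.0, 5.0),), "advance"),        # first onset 70 s > 65 s gap
        (((100.0, 4.0),), "advance"),
        (((20.0, 5.0),), "revert"),         # burrowing resumes inside the gap
        (((64.0, 5.0),), "revert"),
        (((20.0, 5.0), (90.0, 5.0)), "revert"),
        (((10.0, 3.0), (30.0, 3.0)), "revert"),
        (((5.0, 2.0), (60.0, 5.0)), "revert"),
        (((40.0, 10.0),), "revert"),
        (((2.0, 1.0),), "revert"),
    ]
    # absolute reset-anchor times: expulsion at 10 s + the extra's offset
    reset_expect = {
        3: 30.0, 4: 74.0, 5: 100.0, 6: 40.0, 7: 70.0, 8: 50.0, 9: 12.0,
    }
    n_correct = n_total = 0
    for i, (extras, want_cat) in enumerate(layouts):
        for egg_time, want_flag in ((12.0, True), (15.0, False)):
            trial = StimTrial(light_on=5.0, light_off=10.0, egg_out_time=egg_time,
                              pulse_offsets=(6.0, 8.0, 10.0))
            out = classify_post_expulsion(_opto_trial(extras), trial=trial)
            ok = out.category == want_cat and out.expelled_after_stim is want_flag
            if ok and want_cat == "revert":
                ok = abs(out.reset_time - reset_expect[i]) < 0.2
            n_correct += int(ok)
            n_total += 1
    return {"fraction_correct": n_correct / n_total, "n_trials": n_total}


# ---------------------------------------------------------------------------
# Egg-depth recovery
# ---------------------------------------------------------------------------

def depth_recovery(seed: int = 0, n_flies: int = 48) -> dict:
    """Recover per-level mean normalized depth within its 95% binomial CI."""
    records, truth = simulate_egg_depths(n_flies=n_flies, seed=seed)
    by_level: dict[float, list[float]] = {}
    for r in records:
        by_level.setdefault(r.substrate_pct_agarose, []).append(r.depth)
    n_ok = 0
    max_z = 0.0
    for level, depths in by_level.items():
        mu = truth.mean_depth[level]
        pv = truth.depth_probs[level]
        sd = float(np.sqrt(np.dot([0.0, 0.25, 1.0], pv) - mu**2))
        z = abs(np.mean(depths) - mu) / (sd / np.sqrt(len(depths)))
        max_z = max(max_z, float(z))
        n_ok += int(z < 1.96)
    # per-fly summaries must agree with the raw pooled means
    table = egg_output_summary(records)
    assert table["mean_depth"].between(0, 1).all()
    return {
        "levels_within_ci": n_ok,
        "n_levels": len(by_level),
        "max_abs_z": max_z,
    }
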