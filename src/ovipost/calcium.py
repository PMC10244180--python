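"""Paired calcium-imaging / behavior analytics.

Two-channel fluorescence (activity reporter + anatomical marker) is
converted to dF/F0 with a pre-expulsion median baseline that excludes
windows around ovipositor-extrusion events.  Behavioral events are read out
of keypoint distance traces (T6-to-egg before expulsion, T6-to-ovipositor
after), normalized so the median T6-to-analia distance is 1, then high-pass
filtered and total-variation regularized; event onsets are upward crossings
of one-fifth of the regularized signal's maximum.  Response magnitudes are
3-s post-onset integrals, min-max normalized per ROI so a pre-event baseline
maps to 0 and the session maximum to 1.

The 1-D total-variation proximal problem
``min_x 0.5*||x - y||^2 + lam * sum_i |x_{i+1} - x_i|`` is solved exactly
with Condat's direct (non-iterative) algorithm, which keeps noiseless
piecewise-constant inputs piecewise constant — the property the
threshold-crossing detector relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class FluorescenceRecording:
    """Two-channel ROI fluorescence: ``green``/``red`` are (n_roi, n_frames)."""

    green: np.ndarray
    red: np.ndarray
    fps: float = 10.0
    roi_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.green = np.atleast_2d(np.asarray(self.green, dtype=float))
        self.red = np.atleast_2d(np.asarray(self.red, dtype=float))
        if self.green.shape != self.red.shape:
            raise ValueError("green and red channels must have equal shapes")
        if np.any(self.green < 0):
            raise ValueError("raw fluorescence must be nonnegative")
        if not self.roi_ids:
            self.roi_ids = tuple(f"roi{i}" for i in range(self.green.shape[0]))

    @property
    def n_frames(self) -> int:
        return self.green.shape[1]


@dataclass
class DffTrace:
    """Per-ROI dF/F0 with the baseline and its provenance."""

    dff: np.ndarray              # (n_roi, n_frames)
    baseline_f0: np.ndarray      # (n_roi,)
    fps: float
    baseline_mask: np.ndarray = field(default=None)  # frames used for F0

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


@dataclass
class DistanceTraces:
    """Keypoint distances normalized to the median T6-analia distance."""

    t6_egg: np.ndarray
    t6_ovi: np.ndarray
    norm_constant: float
    ovi_egg: Optional[np.ndarray] = None
    fps: float = 10.0


@dataclass(frozen=True)
class DetectedEvent:
    onset_s: float
    type: str = "incomplete_expulsion"   # | complete_expulsion | ovipositor_extrusion
    source: str = "t6_egg"               # | t6_ovi


def _exclusion_mask(n: int, fps: float, centers_s: Sequence[float], half_s: float) -> np.ndarray:
    """True where a frame falls within +-half_s of any center time."""
    mask = np.zeros(n, dtype=bool)
    for c in centers_s:
        lo = max(0, int(np.floor((c - half_s) * fps)))
        hi = min(n, int(np.ceil((c + half_s) * fps)) + 1)
        mask[lo:hi] = True
    return mask


def compute_dff(
    rec: FluorescenceRecording,
    egg_out_time: Optional[float] = None,
    extrusion_events: Sequence[float] = (),
    exclude_s: float = 20.0,
) -> DffTrace:
    """dF/F0 with a pre-expulsion, extrusion-excluded median baseline.

    F0 is the per-ROI median fluorescence from recording onset to
    ``exclude_s`` seconds before completed egg expulsion, further excluding
    ±``exclude_s`` around each ovipositor-extrusion event.  Without an
    expulsion anchor the baseline window is the full trace minus exclusions.
    """
    n = rec.n_frames
    mask = np.ones(n, dtype=bool)
    if egg_out_time is not None:
        cut = int(np.floor((egg_out_time - exclude_s) * rec.fps))
        mask[max(cut, 0):] = False
    mask &= ~_exclusion_mask(n, rec.fps, extrusion_events, exclude_s)
    if not mask.any():
        raise ValueError("baseline window is empty after exclusions")
    f0 = np.median(rec.green[:, mask], axis=1)
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 must be positive")
    dff = (rec.green - f0[:, None]) / f0[:, None]
    return DffTrace(dff=dff, baseline_f0=f0, fps=rec.fps, baseline_mask=mask)


def smooth_display(dff: np.ndarray, k: int = 3) -> np.ndarray:
    """k-point moving average for display only (analysis stays unsmoothed)."""
    kernel = np.ones(k) / k
    arr = np.atleast_2d(dff)
    out = np.stack([np.convolve(row, kernel, mode="same") for row in arr])
    return out if np.ndim(dff) == 2 else out[0]


def normalize_distances(
    t6_egg: np.ndarray,
    t6_ovi: np.ndarray,
    t6_analia: np.ndarray,
    ovi_egg: Optional[np.ndarray] = None,
    fps: float = 10.0,
) -> DistanceTraces:
    """Divide raw pixel distances by the median T6-analia distance.

    The T6-analia segment is a rigid anatomical reference, so its median
    maps to 1 and all distances become scale-free 'analia units'.
    """
    c = float(np.median(t6_analia))
    if c <= 0:
        raise ValueError("median T6-analia distance must be positive")
    return DistanceTraces(
        t6_egg=np.asarray(t6_egg, float) / c,
        t6_ovi=np.asarray(t6_ovi, float) / c,
        ovi_egg=None if ovi_egg is None else np.asarray(ovi_egg, float) / c,
        norm_constant=c,
        fps=fps,
    )


# ---------------------------------------------------------------------------
# Exact 1-D total variation denoising (Condat's direct algorithm)
# ---------------------------------------------------------------------------

def tv_denoise(y: np.ndarray, lam: float) -> np.ndarray:
    """Exact solution of the 1-D TV proximal problem (Condat's algorithm).

    Runs in O(n) typical time with no iteration tolerance; on noiseless
    piecewise-constant input the output is again piecewise constant with no
    spurious levels.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if n == 0 or lam == 0:
        return y.copy()
    x = np.empty(n)
    k = k0 = kminus = kplus = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == n - 1:                            # lone tail sample
            x[k] = vmin + umin
            return x
        if y[k + 1] + umin < vmin - lam:          # negative jump certified
            x[k0 : kminus + 1] = vmin
            k = k0 = kminus = kplus = kminus + 1
            vmin = y[k]
            vmax = y[k] + 2 * lam
            umin = lam
            umax = -lam
            continue
        if y[k + 1] + umax > vmax + lam:          # positive jump certified
            x[k0 : kplus + 1] = vmax
            k = k0 = kminus = kplus = kplus + 1
            vmin = y[k] - 2 * lam
            vmax = y[k]
            umin = lam
            umax = -lam
            continue
        # no jump certified: extend the current segment
        k += 1
        umin += y[k] - vmin
        umax += y[k] - vmax
        if umin >= lam:
            vmin += (umin - lam) / (k - k0 + 1)
            umin = lam
            kminus = k
        if umax <= -lam:
            vmax += (umax + lam) / (k - k0 + 1)
            umax = -lam
            kplus = k
        if k == n - 1:                            # end of signal reached
            if umin < 0:
                x[k0 : kminus + 1] = vmin
                k = k0 = kminus = kminus + 1
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
            elif umax > 0:
                x[k0 : kplus + 1] = vmax
                k = k0 = kplus = kplus + 1
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
            else:
                x[k0:] = vmin + umin / (k - k0 + 1)
                return x


def estimate_noise_sd(y: np.ndarray) -> float:
    """Robust noise sd from the median absolute first difference."""
    d = np.abs(np.diff(np.asarray(y, dtype=float)))
    return float(np.median(d)) / (np.sqrt(2.0) * 0.6745)


def highpass(y: np.ndarray, fps: float, cutoff_hz: float = 0.001) -> np.ndarray:
    """Zero-phase high-pass: subtract a moving-average baseline estimate.

    The baseline is a centered boxcar mean whose length matches the cutoff
    (``N = 0.443 / (cutoff * dt)``, the moving-average -3 dB relation),
    truncated at the trace edges.  At very low cutoffs this reduces to mean
    subtraction, without the edge transients a recursive filter develops
    when its pole sits this close to unity.
    """
    nyq = fps / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    y = np.asarray(y, dtype=float)
    window = max(1, int(round(0.443 * fps / cutoff_hz)))
    n = y.size
    half = min(window, 2 * n) // 2
    c = np.r_[0.0, np.cumsum(y)]
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return y - (c[hi] - c[lo]) / (hi - lo)


def detect_events(
    trace: np.ndarray,
    fps: float = 10.0,
    hp_cutoff: float = 0.001,
    tv_lambda: Optional[float] = None,
    frac: float = 0.2,
    refractory_s: float = 1.0,
    min_snr: float = 4.0,
    event_type: str = "incomplete_expulsion",
    source: str = "t6_egg",
) -> list[DetectedEvent]:
    """Threshold-crossing event detection on a normalized distance trace.

    The trace is zero-phase high-pass filtered (default 0.001 Hz), then TV
    regularized; ``tv_lambda`` defaults to 5x the robust noise sd estimated
    from first differences, strong enough to level noise excursions while
    barely attenuating multi-frame steps.  Onsets are upward crossings of
    ``frac`` x the regularized maximum (default one fifth); crossings within
    ``refractory_s`` of the previous one are merged.  A trace whose
    regularized peak stays under ``min_snr`` noise sds holds no events.
    """
    y = highpass(trace, fps, hp_cutoff)
    sigma = estimate_noise_sd(y)
    lam = 5.0 * sigma if tv_lambda is None else tv_lambda
    reg = tv_denoise(y, lam)
    peak = reg.max()
    if peak <= max(10 * np.finfo(float).eps, min_snr * sigma):
        warnings.warn("regularized trace is flat; no events detected", stacklevel=2)
        return []
    thr = frac * peak
    above = reg > thr
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    events: list[DetectedEvent] = []
    last = -np.inf
    half = max(3, int(round(1.5 * refractory_s * fps)))
    for c in crossings:
        c = int(c)
        for _ in range(3):  # recenter until the step fit is stable
            c2 = _refine_onset(y, c, half=half)
            if c2 == c:
                break
            c = c2
        t = c / fps
        if t - last >= refractory_s:
            events.append(DetectedEvent(onset_s=t, type=event_type, source=source))
            last = t
    return events


def _refine_onset(y: np.ndarray, c: int, half: int = 10) -> int:
    """Least-squares step-position fit in a window around a crossing.

    The TV threshold crossing localizes an event to within a few frames; the
    exact onset is the change point that maximizes the two-sample step
    statistic on the filtered trace, which for an abrupt step at 5:1 SNR is
    correct to within a frame or two almost surely.
    """
    lo = max(0, c - half)
    hi = min(y.size, c + half + 1)
    seg = y[lo:hi]
    if seg.size < 3:
        return c
    best_tau, best_score = c - lo, -np.inf
    csum = np.cumsum(seg)
    total = csum[-1]
    n = seg.size
    for tau in range(1, n):  # step between tau-1 and tau
        n1, n2 = tau, n - tau
        m1 = csum[tau - 1] / n1
        m2 = (total - csum[tau - 1]) / n2
        score = n1 * n2 / n * (m2 - m1) ** 2 * np.sign(m2 - m1)
        if score > best_score:
            best_score, best_tau = score, tau
    return lo + best_tau


# ---------------------------------------------------------------------------
# 3-s integral normalization and event-triggered aggregation
# ---------------------------------------------------------------------------

INTEGRATION_S = 3.0


@dataclass
class NormalizedIntegrals:
    """Per-ROI x per-event 3-s integrals, raw and min-max normalized."""

    raw: np.ndarray           # (n_roi, n_events)
    normalized: np.ndarray    # (n_roi, n_events); anchors map to exactly 0 / 1
    per_roi_mean: np.ndarray  # (n_roi,), mean over events (multi-event reduction)
    anchor0: np.ndarray       # (n_roi,)
    anchor1: np.ndarray       # (n_roi,)
    design: str = "expulsion_context"


def sliding_integral(dff: np.ndarray, fps: float, window_s: float = INTEGRATION_S) -> np.ndarray:
    """Trapezoidal integral of dff over ``[t, t + window_s]`` at every frame.

    Entries whose window would run off the end of the trace are NaN.
    """
    arr = np.atleast_2d(dff)
    w = int(round(window_s * fps))
    cum = np.concatenate(
        [np.zeros((arr.shape[0], 1)), np.cumsum((arr[:, 1:] + arr[:, :-1]) / 2, axis=1)], axis=1
    ) / fps
    out = np.full_like(arr, np.nan, dtype=float)
    if arr.shape[1] > w:
        out[:, : arr.shape[1] - w] = cum[:, w:] - cum[:, : arr.shape[1] - w]
    return out if np.ndim(dff) == 2 else out[0]


def _first_contiguous_median(
    integrals: np.ndarray, valid: np.ndarray, fps: float, stretch_s: float = 60.0
) -> np.ndarray:
    """Median over the first contiguous valid stretch of ``stretch_s``."""
    need = int(round(stretch_s * fps))
    ok = valid & ~np.isnan(integrals[0])
    run = 0
    for i, v in enumerate(ok):
        run = run + 1 if v else 0
        if run >= need:
            sl = slice(i - need + 1, i + 1)
            return np.median(integrals[:, sl], axis=1)
    # fall back to all valid frames when no full stretch exists
    warnings.warn("no contiguous baseline stretch; using all valid frames", stacklevel=3)
    if not ok.any():
        raise ValueError("no valid baseline frames for integral anchor")
    return np.median(integrals[:, ok], axis=1)


def _first_noncontiguous_median(
    integrals: np.ndarray, valid: np.ndarray, fps: float, total_s: float = 60.0
) -> np.ndarray:
    need = int(round(total_s * fps))
    ok = np.flatnonzero(valid & ~np.isnan(integrals[0]))
    if ok.size == 0:
        raise ValueError("no valid baseline frames for integral anchor")
    return np.median(integrals[:, ok[:need]], axis=1)


def integrate_and_normalize(
    dff: DffTrace,
    events: Sequence[DetectedEvent],
    design: str = "expulsion_context",
    egg_out_time: Optional[float] = None,
    exclusion_events: Sequence[float] = (),
    exclude_s: float = 20.0,
) -> NormalizedIntegrals:
    """3-s post-onset integrals, min-max normalized per ROI.

    ``expulsion_context`` (incomplete vs complete expulsion): the 0-anchor is
    the median sliding 3-s integral over the first contiguous 60 s leading up
    to complete expulsion, excluding ±20 s around each expulsion event; the
    1-anchor is the maximum 3-s integral observed throughout (per ROI).

    ``extrusion_context`` (incomplete expulsion vs post-expulsion ovipositor
    extrusion): the 0-anchor is the median over the first 60 s of valid
    (possibly non-contiguous) frames starting 10 s after expulsion, excluding
    ±20 s around extrusion events; the 1-anchor is as above.

    ROIs with multiple events are additionally reduced by the mean.
    """
    if design not in ("expulsion_context", "extrusion_context"):
        raise ValueError(f"unknown design {design!r}")
    fps = dff.fps
    n = dff.n_frames
    integrals = sliding_integral(dff.dff, fps)
    onset_frames = np.array([int(round(ev.onset_s * fps)) for ev in events])
    if np.any(onset_frames < 0) or np.any(onset_frames >= n):
        raise ValueError("event onset outside trace bounds")

    excl = _exclusion_mask(n, fps, exclusion_events, exclude_s)
    t = np.arange(n) / fps
    if design == "expulsion_context":
        if egg_out_time is None:
            raise ValueError("expulsion_context requires egg_out_time")
        valid = (t < egg_out_time) & ~excl
        anchor0 = _first_contiguous_median(integrals, valid, fps)
    else:
        if egg_out_time is None:
            raise ValueError("extrusion_context requires egg_out_time")
        valid = (t >= egg_out_time + 10.0) & ~excl
        anchor0 = _first_noncontiguous_median(integrals, valid, fps)
    anchor1 = np.nanmax(integrals, axis=1)
    rng_ = anchor1 - anchor0

    raw = integrals[:, onset_frames] if onset_frames.size else np.empty((integrals.shape[0], 0))
    if np.isnan(raw).any():
        raise ValueError("an event onset lies too close to the end for a 3-s integral")
    degenerate = np.abs(rng_) < 1e-12
    if degenerate.any():
        # an identically-quiet ROI normalizes to 0 everywhere; anything else
        # with coincident anchors has no dynamic range to normalize by
        if np.any(np.abs(raw[degenerate] - anchor0[degenerate, None]) > 1e-12):
            raise ValueError("normalization anchors coincide (zero dynamic range)")
        rng_ = np.where(degenerate, 1.0, rng_)
    normalized = (raw - anchor0[:, None]) / rng_[:, None]
    per_roi_mean = (
        normalized.mean(axis=1) if normalized.shape[1] else np.full(integrals.shape[0], np.nan)
    )
    return NormalizedIntegrals(
        raw=raw,
        normalized=normalized,
        per_roi_mean=per_roi_mean,
        anchor0=anchor0,
        anchor1=anchor1,
        design=design,
    )


def postexpulsion_median_integral(
    dff: DffTrace, egg_out_time: float, lo_s: float = 10.0, hi_s: float = 20.0
) -> np.ndarray:
    """Median 3-s integral in ``[egg_out + lo_s, egg_out + hi_s]`` per ROI."""
    integrals = sliding_integral(dff.dff, dff.fps)
    t = np.arange(dff.n_frames) / dff.fps
    sel = (t >= egg_out_time + lo_s) & (t <= egg_out_time + hi_s) & ~np.isnan(integrals[0])
    if not sel.any():
        raise ValueError("post-expulsion window has no valid integrals")
    return np.median(integrals[:, sel], axis=1)


def event_triggered_average(
    dff: DffTrace,
    events: Sequence[DetectedEvent],
    window_s: tuple[float, float] = (-10.0, 20.0),
) -> dict:
    """Event-aligned snippets pooled over ROIs and events, with mean ± s.e.m.

    Snippets extending past the recording edges are padded with NaN, which
    the pooled mean and standard error ignore.
    """
    if not events:
        raise ValueError("no events to align to")
    fps = dff.fps
    lo = int(round(window_s[0] * fps))
    hi = int(round(window_s[1] * fps))
    rel = np.arange(lo, hi + 1)
    snippets = []
    for ev in events:
        c = int(round(ev.onset_s * fps))
        idx = c + rel
        ok = (idx >= 0) & (idx < dff.n_frames)
        for row in dff.dff:
            s = np.full(rel.size, np.nan)
            s[ok] = row[idx[ok]]
            snippets.append(s)
    snip = np.array(snippets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(snip, axis=0)
        sd = np.nanstd(snip, axis=0, ddof=1) if snip.shape[0] > 1 else np.zeros(rel.size)
        count = np.sum(~np.isnan(snip), axis=0)
    sem = np.where(count > 0, sd / np.sqrt(np.maximum(count, 1)), np.nan)
    if snip.shape[0] == 1:
        sem = np.zeros(rel.size)
    return {"times_s": rel / fps, "snippets": snip, "mean": mean, "sem": sem}
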