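"""Pose-derived feature extraction for unsupervised behavior mapping.

From tracked keypoints (standard three-header-row pose-estimation CSV
dialect: scorer / bodypart / coordinate, with x, y, likelihood triplets per
bodypart) this module derives the 17 per-frame features used for behavior
mapping:

=========  ==============================================================
vel        scutellum speed, displacement across a 10-frame (500 ms) lag
pe         per-frame movement of the proboscis tip relative to the ocellus
ba         z-scored signed angle between the ventral abdominal-stripe line
           (A2 -> A6) and the body axis line (ocellus -> scutellum)
velba      per-frame angular velocity of that angle, z-scored
T1..T3     per-frame movement of each leg joint
Pegg       pose-model prediction confidence for egg emergence
w1ovi      0.8-1.3 Hz Morlet band magnitude of the ovipositor ROI intensity
w2ovi      1.3-2.3 Hz Morlet band magnitude of the same trace
cwt1..7    log Morlet magnitudes of A5-stripe movement at seven log-spaced
           center frequencies spanning 0.5-10 Hz
=========  ==============================================================

A threshold-based walking classifier (speed smoothed by a 1-s moving
average, threshold 0.29 mm/s) lives here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pywt

from .ethogram import _runs

#: Bodyparts required for the full 17-feature set.
REQUIRED_BODYPARTS: tuple[str, ...] = (
    "scutellum", "ocellus", "proboscis_tip", "stripe_A2", "stripe_A5",
    "stripe_A6", "leg_T1", "leg_T2", "leg_T3", "ovipositor", "T6_edge",
    "egg_tip", "analia_base",
)

#: Fixed column order of the assembled feature matrix.
FEATURE_COLUMNS: tuple[str, ...] = (
    "vel", "pe", "ba", "velba", "T1", "T2", "T3", "Pegg",
    "w1ovi", "w2ovi", "cwt1", "cwt2", "cwt3", "cwt4", "cwt5", "cwt6", "cwt7",
)

#: Morlet band edges (Hz) for the ovipositor ROI-intensity channels.
OVI_BANDS: tuple[tuple[float, float], ...] = ((0.8, 1.3), (1.3, 2.3))

#: Complex Morlet with the classic 6-cycle carrier (B=2, C=6/(2*pi)).
MORLET = "cmor2.0-0.9549"

LOG_FLOOR = 1e-6


@dataclass
class KeypointTrack:
    """Frame-indexed keypoint positions with tracking confidence.

    ``points[name]`` is an ``(n_frames, 3)`` float array of (x px, y px,
    confidence).  ``interpolated`` records, per bodypart, the spans whose
    low-confidence coordinates were filled in.
    """

    points: dict[str, np.ndarray]
    fps: float = 20.0
    px_per_mm: float = 20.0
    interpolated: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {v.shape[0] for v in self.points.values()}
        if len(lengths) > 1:
            raise ValueError("all bodyparts must have equal frame counts")
        for name, arr in self.points.items():
            conf = arr[:, 2]
            if np.any((conf < 0) | (conf > 1)):
                raise ValueError(f"{name}: confidence outside [0, 1]")

    @property
    def n_frames(self) -> int:
        return next(iter(self.points.values())).shape[0] if self.points else 0

    def xy(self, name: str) -> np.ndarray:
        if name not in self.points:
            raise KeyError(f"required bodypart {name!r} missing from track")
        return self.points[name][:, :2]

    def confidence(self, name: str) -> np.ndarray:
        if name not in self.points:
            raise KeyError(f"required bodypart {name!r} missing from track")
        return self.points[name][:, 2]


# ---------------------------------------------------------------------------
# Keypoint CSV dialect (three header rows: scorer / bodyparts / coords)
# ---------------------------------------------------------------------------

def read_keypoints(
    path: str | Path,
    px_per_mm: float = 20.0,
    fps: float = 20.0,
    min_confidence: float = 0.9,
) -> KeypointTrack:
    """Read a three-header-row keypoint CSV into a :class:`KeypointTrack`.

    Frames with tracking confidence below ``min_confidence`` have their
    coordinates linearly interpolated from the neighboring confident frames;
    leading/trailing gaps are held at the nearest confident value.  The
    interpolated spans are recorded in the track's provenance.
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed keypoint CSV header ({exc})") from exc
    if df.columns.nlevels != 3:
        raise ValueError(f"{path}: expected three header rows")
    points: dict[str, np.ndarray] = {}
    interpolated: dict[str, list[tuple[int, int]]] = {}
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    for bp in bodyparts:
        sub = df.xs(bp, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        for coord in ("x", "y", "likelihood"):
            if coord not in sub.columns:
                raise ValueError(f"{path}: bodypart {bp!r} missing {coord!r} column")
        arr = sub[["x", "y", "likelihood"]].to_numpy(dtype=float)
        arr, spans = _interpolate_low_confidence(arr, min_confidence)
        points[bp] = arr
        if spans:
            interpolated[bp] = spans
    return KeypointTrack(points=points, fps=fps, px_per_mm=px_per_mm, interpolated=interpolated)


def write_keypoints(track: KeypointTrack, path: str | Path, scorer: str = "ovipost") -> Path:
    """Write a track in the same three-header-row CSV dialect."""
    cols = {}
    for bp, arr in track.points.items():
        for j, coord in enumerate(("x", "y", "likelihood")):
            cols[(scorer, bp, coord)] = arr[:, j]
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["scorer", "bodyparts", "coords"])
    df.index.name = "coords"
    df.to_csv(path)
    return Path(path)


def _interpolate_low_confidence(
    arr: np.ndarray, min_confidence: float
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    arr = arr.copy()
    bad = arr[:, 2] < min_confidence
    if not bad.any() or bad.all():
        return arr, [(0, arr.shape[0])] if bad.all() else []
    good_idx = np.flatnonzero(~bad)
    all_idx = np.arange(arr.shape[0])
    for j in (0, 1):
        arr[:, j] = np.interp(all_idx, good_idx, arr[good_idx, j])
    starts, ends = _runs(bad)
    return arr, [(int(s), int(t)) for s, t in zip(starts, ends)]


# ---------------------------------------------------------------------------
# Kinematic channels
# ---------------------------------------------------------------------------

def zscore(x: np.ndarray) -> np.ndarray:
    """Population z-score; a constant channel maps to all zeros."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _frame_displacement(xy: np.ndarray) -> np.ndarray:
    """Per-frame Euclidean displacement in px/frame (first frame = 0)."""
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return np.r_[0.0, d]


def _body_angle(track: KeypointTrack) -> np.ndarray:
    """Signed angle (rad) between the A2->A6 stripe line and the body axis."""
    ab = track.xy("stripe_A6") - track.xy("stripe_A2")
    ax = track.xy("scutellum") - track.xy("ocellus")
    cross = ab[:, 0] * ax[:, 1] - ab[:, 1] * ax[:, 0]
    dot = (ab * ax).sum(axis=1)
    return np.arctan2(cross, dot)


def kinematic_features(track: KeypointTrack, speed_lag_frames: int = 10) -> dict[str, np.ndarray]:
    """Named kinematic channels from a keypoint track.

    ``vel`` is the scutellum displacement across ``speed_lag_frames`` frames
    divided by the lag duration (px/s; divide by ``px_per_mm`` for mm/s) —
    the lag (default 10 frames = 500 ms at 20 Hz) suppresses jitter.  The
    movement channels (``pe``, ``T1``-``T3``, ``A5_move``) are per-frame
    Euclidean displacements in px/frame.  ``ba`` is the per-recording
    z-scored body-bend angle and ``velba`` its per-frame derivative,
    z-scored after differencing.
    """
    n = track.n_frames
    if n <= speed_lag_frames:
        raise ValueError(f"track length {n} <= speed lag {speed_lag_frames}")
    scu = track.xy("scutellum")
    disp = np.linalg.norm(scu[speed_lag_frames:] - scu[:-speed_lag_frames], axis=1)
    vel = np.empty(n)
    vel[speed_lag_frames:] = disp / (speed_lag_frames / track.fps)
    vel[:speed_lag_frames] = vel[speed_lag_frames]

    angle = np.unwrap(_body_angle(track))
    dangle = np.r_[0.0, np.diff(angle)]
    return {
        "vel": vel,
        "pe": _frame_displacement(track.xy("proboscis_tip") - track.xy("ocellus")),
        "ba": zscore(angle),
        "velba": zscore(dangle),
        "T1": _frame_displacement(track.xy("leg_T1")),
        "T2": _frame_displacement(track.xy("leg_T2")),
        "T3": _frame_displacement(track.xy("leg_T3")),
        "A5_move": _frame_displacement(track.xy("stripe_A5")),
        "Pegg": track.confidence("egg_tip").copy(),
    }


# ---------------------------------------------------------------------------
# Walking classifier
# ---------------------------------------------------------------------------

def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation.

    The window covers ``[t - window//2, t + window//2]`` inclusive, clipped
    at the trace boundaries, and averages over the samples available.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    n = x.size
    half = window // 2
    c = np.r_[0.0, np.cumsum(x)]
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def walking_bouts(
    vel_mm_s: np.ndarray,
    fps: float = 20.0,
    threshold: float = 0.29,
    smooth_s: float = 1.0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Classify walking frames: smoothed speed strictly above threshold.

    Speed (mm/s) is smoothed by a centered ``smooth_s`` moving average
    before thresholding at 0.29 mm/s.  Returns the boolean walk channel and
    its bouts as half-open frame intervals.
    """
    if smooth_s <= 0:
        raise ValueError("smoothing window must be positive")
    window = max(1, int(round(smooth_s * fps)))
    walk = moving_average(vel_mm_s, window) > threshold
    starts, ends = _runs(walk)
    return walk, [(int(s), int(t)) for s, t in zip(starts, ends)]


# ---------------------------------------------------------------------------
# Morlet wavelet band features
# ---------------------------------------------------------------------------

def morlet_magnitude(signal: np.ndarray, fps: float, freqs: Sequence[float]) -> np.ndarray:
    """Complex-Morlet CWT magnitude at the given center frequencies (Hz).

    Returns an ``(n_freqs, n_frames)`` array.  The signal is mean-subtracted
    first, so a constant trace has magnitude ~0 everywhere.
    """
    freqs = np.asarray(freqs, dtype=float)
    nyquist = fps / 2.0
    if np.any(freqs > nyquist * (1 + 1e-9)):
        raise ValueError(f"frequency above Nyquist ({nyquist} Hz): {freqs.max()} Hz")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    fc = pywt.central_frequency(MORLET)
    scales = fc * fps / freqs
    coefs, _ = pywt.cwt(x, scales, MORLET, sampling_period=1.0 / fps)
    return np.abs(coefs)


def band_frequencies(low: float, high: float, n: int = 4) -> np.ndarray:
    """Log-spaced sampling frequencies inside a band (edges included)."""
    return np.geomspace(low, high, n)


def morlet_band_features(
    signal: np.ndarray,
    fps: float,
    bands: Sequence[tuple[float, float]] = OVI_BANDS,
    log_output: bool = False,
    n_freqs_per_band: int = 4,
) -> np.ndarray:
    """Mean Morlet magnitude per frequency band, ``(n_bands, n_frames)``.

    Each band channel averages the CWT magnitude over ``n_freqs_per_band``
    log-spaced frequencies spanning the band.  With ``log_output`` the
    natural log of the magnitude is returned, floored at a small epsilon.
    """
    out = []
    for low, high in bands:
        if not 0 < low < high:
            raise ValueError(f"bad band ({low}, {high})")
        mag = morlet_magnitude(signal, fps, band_frequencies(low, high, n_freqs_per_band))
        out.append(mag.mean(axis=0))
    res = np.stack(out)
    if log_output:
        res = np.log(np.maximum(res, LOG_FLOOR))
    return res


def a5_center_frequencies(low: float = 0.5, high: float = 10.0, n: int = 7) -> np.ndarray:
    """The seven log-spaced center frequencies of the A5-movement channels."""
    return np.geomspace(low, high, n)


# ---------------------------------------------------------------------------
# Feature-matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Frame x 17 named feature table (fixed column order) plus frame rate."""

    data: pd.DataFrame
    fps: float
    ovi_fallback: bool = False

    def __post_init__(self) -> None:
        if tuple(self.data.columns) != FEATURE_COLUMNS:
            raise ValueError(f"feature columns must be {FEATURE_COLUMNS}")
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains NaN after assembly")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def zscored(self) -> np.ndarray:
        """Column-wise z-scored array, ready for embedding."""
        return np.column_stack([zscore(self.data[c].to_numpy()) for c in self.data.columns])


def build_feature_matrix(
    track: KeypointTrack,
    ovi_intensity: Optional[np.ndarray] = None,
    speed_lag_frames: int = 10,
) -> FeatureMatrix:
    """Assemble the 17-column feature matrix from a track (+ ROI intensity).

    ``w1ovi``/``w2ovi`` come from the ovipositor ROI mean-intensity trace
    (supplied by the video pipeline or the simulator).  When that trace is
    absent, the wavelet bands are computed from the ovipositor keypoint
    displacement instead and the matrix is flagged (``ovi_fallback``).
    ``cwt1``-``cwt7`` are log Morlet magnitudes of A5-stripe movement at
    seven log-spaced center frequencies from 0.5 to 10 Hz.
    """
    kin = kinematic_features(track, speed_lag_frames=speed_lag_frames)
    fallback = ovi_intensity is None
    if fallback:
        ovi_signal = _frame_displacement(track.xy("ovipositor"))
    else:
        ovi_signal = np.asarray(ovi_intensity, dtype=float)
        if ovi_signal.shape[0] != track.n_frames:
            raise ValueError("ovi_intensity length must match the track")
    w = morlet_band_features(ovi_signal, track.fps, OVI_BANDS, log_output=False)
    centers = a5_center_frequencies()
    usable = centers <= track.fps / 2 * (1 + 1e-9)
    cwt = np.full((len(centers), track.n_frames), np.log(LOG_FLOOR))
    if usable.any():
        mag = morlet_magnitude(kin["A5_move"], track.fps, centers[usable])
        cwt[usable] = np.log(np.maximum(mag, LOG_FLOOR))
    cols = {
        "vel": kin["vel"], "pe": kin["pe"], "ba": kin["ba"], "velba": kin["velba"],
        "T1": kin["T1"], "T2": kin["T2"], "T3": kin["T3"], "Pegg": kin["Pegg"],
        "w1ovi": w[0], "w2ovi": w[1],
    }
    for i in range(7):
        cols[f"cwt{i + 1}"] = cwt[i]
    df = pd.DataFrame(cols, columns=list(FEATURE_COLUMNS))
    return FeatureMatrix(data=df, fps=track.fps, ovi_fallback=fallback)
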