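"""Synthetic data with known ground truth for every pipeline stage.

Raw video and imaging data behind egg-laying studies are rarely small enough
to redistribute, so every analysis here is exercised against generators that
emulate the relevant structure of the real recordings:

* semi-Markov ethograms — behavior onsets drawn from a 7 x 7 start-to-start
  transition matrix with gamma dwell times, burrow bouts carrying rhythmic
  cycles with a per-cycle abort probability, one completed egg expulsion per
  event, and the bend-overlap convention (an abdominal bend is maintained
  throughout burrowing, expulsion and detachment);
* keypoint tracks whose kinematics express the walking / bending /
  burrowing / egg-emergence signatures the 17-feature extractor looks for,
  including an ovipositor ROI-intensity oscillation that slows in frequency
  across each burrowing episode;
* two-channel fluorescence with double-exponential transients locked to
  behavioral events, shared slow drift, and step-like distance traces;
* per-fly egg-depth tables versus substrate firmness;
* well-separated feature-space motifs for the behavior-map benchmarks.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calcium import FluorescenceRecording
from .episodes import EggRecord
from .ethogram import LABELS, LABEL_INDEX, Ethogram
from .features import KeypointTrack

#: Behaviors an abdominal bend is maintained through.
_BEND_COVERS = {"burrow", "egg_out", "detach"}


def default_transition_matrix() -> np.ndarray:
    """Default start-to-start transition matrix for simulated events.

    Qualitatively mirrors the significant arrows of the real sequence — an
    exploration loop between proboscis extension and walking, walk -> bend,
    bend -> burrow, a burrow self-loop (abort and reinitiate), burrow ->
    egg out -> detach -> groom — with free parameter values.
    """
    m = np.zeros((7, 7))

    def set_row(lab: str, **probs: float) -> None:
        for k, v in probs.items():
            m[LABEL_INDEX[lab], LABEL_INDEX[k]] = v

    set_row("pe", pe=0.30, walk=0.55, bend=0.15)
    set_row("walk", pe=0.50, walk=0.30, bend=0.20)
    set_row("bend", walk=0.12, burrow=0.88)
    set_row("burrow", pe=0.10, walk=0.15, burrow=0.60, egg_out=0.15)
    set_row("egg_out", detach=0.85, groom=0.15)
    set_row("detach", walk=0.20, detach=0.10, groom=0.70)
    set_row("groom", pe=0.20, walk=0.45, groom=0.35)
    assert np.allclose(m.sum(axis=1), 1.0)
    return m


#: Gamma dwell-time (shape, scale) in seconds per behavior.
DEFAULT_DWELLS: dict[str, tuple[float, float]] = {
    "pe": (2.0, 0.4),
    "walk": (2.0, 0.8),
    "bend": (3.0, 0.4),
    "burrow": (3.0, 1.2),   # used only when cycle-driven durations are off
    "egg_out": (2.0, 0.5),
    "detach": (2.0, 0.5),
    "groom": (2.0, 1.0),
}


@dataclass
class EthogramSimParams:
    """Parameters of the semi-Markov ethogram generator."""

    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    dwell_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DWELLS)
    )
    initial_distribution: Optional[np.ndarray] = None  # default: pe/walk 50/50
    cycle_rate: float = 1.2            # burrow cycles per second
    p_abort_per_cycle: float = 0.25    # geometric cycle count per episode
    fps: float = 20.0
    max_post_items: int = 10           # onsets kept after egg expulsion
    tail_s: float = 8.0                # quiet recording tail after the last bout
    include_location: bool = False
    walk_speed_mm_s: float = 3.0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (7, 7) or not np.allclose(
            self.transition_matrix.sum(axis=1), 1.0
        ):
            raise ValueError("transition_matrix must be 7x7 row-stochastic")
        for lab, (shape, scale) in self.dwell_distributions.items():
            if shape <= 0 or scale <= 0:
                raise ValueError(f"dwell parameters for {lab} must be positive")
        if self.initial_distribution is None:
            init = np.zeros(7)
            init[LABEL_INDEX["pe"]] = 0.5
            init[LABEL_INDEX["walk"]] = 0.5
            self.initial_distribution = init


@dataclass
class GroundTruth:
    """Generator-side record of what was emitted, for recovery assertions."""

    items: Optional[list[tuple[str, int]]] = None       # chain onsets
    transition_matrix: Optional[np.ndarray] = None
    episodes: Optional[list[dict]] = None               # burrow episodes
    walk_frames: Optional[np.ndarray] = None
    burrow_frequency_hz: Optional[np.ndarray] = None
    event_onsets_s: Optional[np.ndarray] = None
    event_types: Optional[list[str]] = None
    motif_labels: Optional[np.ndarray] = None
    depth_probs: Optional[dict] = None
    mean_depth: Optional[dict] = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Semi-Markov ethograms
# ---------------------------------------------------------------------------

def _sample_chain(p: EthogramSimParams, rng: np.random.Generator) -> list[str]:
    """One event's onset-label chain: pre phase up to egg_out, then post.

    The event ends after ``max_post_items`` post-expulsion onsets, or just
    before a second egg expulsion would occur (the next egg starts the next
    event).
    """
    egg = LABEL_INDEX["egg_out"]
    matrix = p.transition_matrix
    if p.p_abort_per_cycle == 0:
        # no episode ever aborts: burrowing always runs through to expulsion
        matrix = matrix.copy()
        matrix[LABEL_INDEX["burrow"]] = 0.0
        matrix[LABEL_INDEX["burrow"], egg] = 1.0
    state = int(rng.choice(7, p=p.initial_distribution))
    chain = [state]
    while state != egg:
        state = int(rng.choice(7, p=matrix[state]))
        chain.append(state)
    for _ in range(p.max_post_items):
        nxt = int(rng.choice(7, p=matrix[state]))
        if nxt == egg:
            break
        chain.append(nxt)
        state = nxt
    # a trailing burrow bout belongs to the next egg's deposition attempt:
    # truncating mid-episode would fabricate an aborted episode
    while len(chain) > 1 and chain[-1] == LABEL_INDEX["burrow"]:
        chain.pop()
    return [LABELS[i] for i in chain]


def simulate_ethogram(
    p: EthogramSimParams, seed: int = 0, fly_id: str = "fly0", event_id: str = "ev0"
) -> tuple[Ethogram, GroundTruth]:
    """Simulate one egg-laying event as a validated multi-label ethogram.

    Onsets follow the start-transition chain; each bout occupies the frames
    up to one frame before the next onset, so consecutive same-label onsets
    yield distinct bouts.  Burrow bout durations are cycle-driven: the cycle
    count is geometric with per-cycle continuation probability
    ``1 - p_abort_per_cycle`` and the duration is ``n_cycles / cycle_rate``,
    which makes episode duration proportional to cycle count by
    construction.  Egg expulsion is a single frame placed at the closing
    frame of its burrow episode; bend activity is extended over consecutive
    burrow / egg-out / detach bouts.
    """
    rng = np.random.default_rng(seed)
    labels = _sample_chain(p, rng)
    fps = p.fps

    onsets: list[int] = []
    ends: list[int] = []  # active end (exclusive) of each item's own bout
    truth_episodes: list[dict] = []
    t = 0
    for i, lab in enumerate(labels):
        if lab == "burrow":
            p_stop = p.p_abort_per_cycle if p.p_abort_per_cycle > 0 else 0.25
            n_cyc = int(rng.geometric(p_stop))
            dwell_s = n_cyc / p.cycle_rate + rng.normal(0.0, 0.05)
        elif lab == "egg_out":
            n_cyc = 0
            shape, scale = p.dwell_distributions[lab]
            dwell_s = rng.gamma(shape, scale)
        else:
            n_cyc = 0
            shape, scale = p.dwell_distributions[lab]
            dwell_s = rng.gamma(shape, scale)
        d = max(3, int(round(dwell_s * fps)))
        if lab == "egg_out" and i > 0 and labels[i - 1] == "burrow":
            # expulsion closes the burrow episode: place it on the episode's
            # final frame rather than after the inter-onset gap
            t = max(ends[-1], onsets[-1] + 1)
        onsets.append(t)
        if lab == "egg_out":
            ends.append(t + 1)
        else:
            ends.append(t + d - 1)
        if lab == "burrow":
            truth_episodes.append(
                {"start": t, "end": t + d - 1, "n_cycles": max(1, n_cyc), "outcome": "abort"}
            )
        t = t + d

    n_frames = ends[-1] + int(round(p.tail_s * fps))
    act = np.zeros((n_frames, 7), dtype=bool)
    egg_frame: Optional[int] = None
    for i, lab in enumerate(labels):
        act[onsets[i] : ends[i], LABEL_INDEX[lab]] = True
        if lab == "egg_out":
            egg_frame = onsets[i]
    # bend maintained throughout consecutive burrow / egg-out / detach bouts
    for i, lab in enumerate(labels):
        if lab != "bend":
            continue
        j = i + 1
        cover_end = ends[i]
        while j < len(labels) and labels[j] in _BEND_COVERS:
            cover_end = max(cover_end, ends[j])
            j += 1
        act[onsets[i] : cover_end, LABEL_INDEX["bend"]] = True

    # rhythmic cycles within each burrow episode
    cycle_frames: list[int] = []
    for ep in truth_episodes:
        span = ep["end"] - ep["start"]
        n_cyc = min(ep["n_cycles"], span)
        pos = ep["start"] + ((np.arange(n_cyc) + 0.5) / n_cyc * span).astype(int)
        pos = np.unique(np.clip(pos, ep["start"], ep["end"] - 1))
        ep["cycle_frames"] = [int(c) for c in pos]
        cycle_frames.extend(ep["cycle_frames"])
        if egg_frame is not None and ep["start"] <= egg_frame <= ep["end"]:
            ep["outcome"] = "expel"

    location = None
    if p.include_location:
        heading = np.cumsum(rng.normal(0, 0.1, n_frames))
        speed = np.where(act[:, LABEL_INDEX["walk"]], p.walk_speed_mm_s / fps, 0.0)
        steps = np.column_stack([speed * np.cos(heading), speed * np.sin(heading)])
        location = np.cumsum(steps, axis=0)

    e = Ethogram(
        activity=act,
        fps=fps,
        fly_id=fly_id,
        event_id=event_id,
        cycle_frames=np.array(sorted(cycle_frames), dtype=int),
        egg_out_frame=egg_frame,
        location_track=location,
    )
    truth = GroundTruth(
        items=list(zip(labels, onsets)),
        transition_matrix=p.transition_matrix.copy(),
        episodes=truth_episodes,
        walk_frames=np.flatnonzero(act[:, LABEL_INDEX["walk"]]),
    )
    return e, truth


def simulate_cohort(
    p: EthogramSimParams,
    n_events: int = 20,
    n_flies: int = 5,
    seed: int = 0,
) -> tuple[list[Ethogram], list[GroundTruth]]:
    """A cohort of events distributed round-robin over flies."""
    seeds = np.random.SeedSequence(seed).generate_state(n_events)
    ethos, truths = [], []
    for i in range(n_events):
        e, g = simulate_ethogram(
            p, seed=int(seeds[i] % (2**31)), fly_id=f"fly{i % n_flies}", event_id=f"ev{i}"
        )
        ethos.append(e)
        truths.append(g)
    return ethos, truths


# ---------------------------------------------------------------------------
# Keypoint tracks
# ---------------------------------------------------------------------------

#: Resting skeleton keypoint positions (px), lateral aspect.
_SKELETON: dict[str, tuple[float, float]] = {
    "proboscis_tip": (-12.0, 2.0),
    "ocellus": (0.0, 0.0),
    "scutellum": (30.0, 2.0),
    "leg_T1": (8.0, 18.0),
    "leg_T2": (18.0, 20.0),
    "leg_T3": (28.0, 22.0),
    "stripe_A2": (42.0, 8.0),
    "stripe_A5": (60.0, 12.0),
    "stripe_A6": (66.0, 13.0),
    "T6_edge": (70.0, 14.0),
    "analia_base": (74.0, 15.0),
    "ovipositor": (78.0, 16.0),
    "egg_tip": (80.0, 18.0),
}


@dataclass
class KeypointSimParams:
    px_per_mm: float = 20.0
    walk_speed_mm_s: float = 3.0
    bend_angle_rad: float = 0.7
    bend_ramp_s: float = 1.0
    pe_amplitude_px: float = 6.0
    pe_freq_hz: float = 2.0
    leg_amplitude_px: float = 3.0
    jitter_px: float = 0.2
    ovi_baseline: float = 500.0
    ovi_osc_amplitude: float = 60.0
    burrow_freq_start_hz: float = 2.0
    burrow_freq_end_hz: float = 0.8
    pegg_rise_s: float = 2.0
    pegg_floor: float = 0.02


def simulate_keypoints(
    e: Ethogram, p: Optional[KeypointSimParams] = None, seed: int = 0
) -> tuple[KeypointTrack, np.ndarray, GroundTruth]:
    """Keypoint trajectories + ovipositor ROI intensity realizing an ethogram.

    Walking translates the whole body at the configured speed; bending
    rotates the abdominal keypoints about the A2 stripe; burrowing drives a
    sinusoidal ROI-intensity oscillation whose frequency falls linearly from
    ``burrow_freq_start_hz`` to ``burrow_freq_end_hz`` across each episode
    (the oscillation slows as the egg incrementally emerges); the
    egg-emergence confidence ramps to 1 approaching expulsion.  Gaussian
    jitter is added to every keypoint.
    """
    if p is None:
        p = KeypointSimParams()
    rng = np.random.default_rng(seed)
    n = e.n_frames
    fps = e.fps

    walk = e.column("walk")
    heading = np.cumsum(rng.normal(0, 0.05, n))
    step = np.where(walk, p.walk_speed_mm_s * p.px_per_mm / fps, 0.0)
    body = np.cumsum(np.column_stack([step * np.cos(heading), step * np.sin(heading)]), axis=0)

    # abdominal bend angle ramps up at bend onset and holds
    bend = e.column("bend")
    angle = np.zeros(n)
    ramp = max(1, int(round(p.bend_ramp_s * fps)))
    run = 0
    for i in range(n):
        run = run + 1 if bend[i] else 0
        angle[i] = p.bend_angle_rad * min(run, ramp) / ramp

    # ovipositor ROI intensity: oscillation slowing across each burrow episode
    burrow = e.column("burrow")
    freq = np.zeros(n)
    phase = np.zeros(n)
    from .ethogram import _runs  # local import to avoid cycle at module load

    starts, ends_ = _runs(burrow)
    for s, t in zip(starts, ends_):
        L = t - s
        f = np.linspace(p.burrow_freq_start_hz, p.burrow_freq_end_hz, L)
        freq[s:t] = f
        phase[s:t] = 2 * np.pi * np.cumsum(f) / fps
    ovi_intensity = p.ovi_baseline + np.where(burrow, p.ovi_osc_amplitude * np.sin(phase), 0.0)

    # egg-emergence confidence
    pegg = np.full(n, p.pegg_floor)
    if e.egg_out_frame is not None:
        rise = int(round(p.pegg_rise_s * fps))
        g = int(e.egg_out_frame)
        lo = max(0, g - rise)
        pegg[lo : g + 1] = np.linspace(p.pegg_floor, 1.0, g + 1 - lo)
        hold = min(n, g + int(fps))
        pegg[g:hold] = 1.0
        if hold < n:
            decay = np.exp(-np.arange(n - hold) / fps)
            pegg[hold:] = p.pegg_floor + (1.0 - p.pegg_floor) * decay

    pe_act = e.column("pe")
    groom = e.column("groom")
    tvec = np.arange(n) / fps
    points: dict[str, np.ndarray] = {}
    pivot = np.array(_SKELETON["stripe_A2"])
    abdominal = {"stripe_A5", "stripe_A6", "T6_edge", "analia_base", "ovipositor", "egg_tip"}
    cos_a, sin_a = np.cos(angle), np.sin(angle)
    for name, (x0, y0) in _SKELETON.items():
        base = np.tile([x0, y0], (n, 1)).astype(float)
        if name in abdominal:
            rel = np.array([x0, y0]) - pivot
            base[:, 0] = pivot[0] + rel[0] * cos_a - rel[1] * sin_a
            base[:, 1] = pivot[1] + rel[0] * sin_a + rel[1] * cos_a
        if name == "proboscis_tip":
            ext = np.where(pe_act, p.pe_amplitude_px * np.abs(np.sin(2 * np.pi * p.pe_freq_hz * tvec)), 0.0)
            base[:, 0] -= ext
        if name.startswith("leg_"):
            moving = walk | groom
            base += np.where(
                moving[:, None], rng.normal(0, p.leg_amplitude_px, (n, 2)), 0.0
            )
        base += body
        if p.jitter_px > 0:
            base += rng.normal(0, p.jitter_px, (n, 2))
        conf = pegg if name == "egg_tip" else np.full(n, 0.99)
        points[name] = np.column_stack([base, conf])

    track = KeypointTrack(points=points, fps=fps, px_per_mm=p.px_per_mm)
    truth = GroundTruth(
        walk_frames=np.flatnonzero(walk),
        burrow_frequency_hz=freq,
        extra={"ovi_baseline": p.ovi_baseline, "bend_angle": angle},
    )
    return track, ovi_intensity, truth


# ---------------------------------------------------------------------------
# Fluorescence and distance traces
# ---------------------------------------------------------------------------

@dataclass
class FluorSimParams:
    rise_tau_s: float = 0.15
    decay_tau_s: float = 0.8
    amplitude_dff: float = 1.0
    noise_sd: float = 2.0        # fluorescence units
    baseline_f: float = 100.0
    drift_amplitude: float = 2.0
    drift_period_s: float = 120.0
    red_level: float = 80.0
    step_height: float = 1.0     # distance-step height (normalized units)
    step_duration_s: float = 2.0
    distance_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if min(self.rise_tau_s, self.decay_tau_s, self.amplitude_dff, self.baseline_f) <= 0:
            raise ValueError("kernel taus, amplitude and baseline must be positive")
        if self.noise_sd < 0 or self.distance_noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


def transient_kernel(fps: float, p: FluorSimParams, duration_s: float = 8.0) -> np.ndarray:
    """Double-exponential calcium transient, peak-normalized to the amplitude."""
    t = np.arange(0, duration_s, 1.0 / fps)
    k = np.exp(-t / p.decay_tau_s) - np.exp(-t / p.rise_tau_s)
    return p.amplitude_dff * k / k.max()


def simulate_fluorescence(
    event_onsets_s: Sequence[float],
    event_types: Optional[Sequence[str]] = None,
    p: Optional[FluorSimParams] = None,
    fps: float = 10.0,
    duration_s: float = 300.0,
    n_roi: int = 1,
    seed: int = 0,
) -> tuple[FluorescenceRecording, dict[str, np.ndarray], GroundTruth]:
    """Event-locked two-channel fluorescence plus keypoint distance traces.

    The activity channel is baseline + double-exponential transients at the
    event onsets + slow sinusoidal drift + white noise; the anatomical
    channel shares the drift but has no transients.  Distance traces carry a
    rectangular excursion of ``step_height`` for ``step_duration_s`` at each
    event onset (egg advance then retreat), routed to the T6-egg trace for
    expulsion-type events and to the T6-ovipositor trace for extrusions.
    """
    if p is None:
        p = FluorSimParams()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    onsets = np.asarray(event_onsets_s, dtype=float)
    if np.any((onsets < 0) | (onsets >= duration_s)):
        raise ValueError("event onsets must lie within the recording")
    types = list(event_types) if event_types is not None else ["incomplete_expulsion"] * len(onsets)

    kernel = transient_kernel(fps, p)
    clean = np.zeros(n)
    for t0 in onsets:
        i0 = int(round(t0 * fps))
        seg = min(kernel.size, n - i0)
        clean[i0 : i0 + seg] += kernel[:seg]
    drift = p.drift_amplitude * np.sin(2 * np.pi * np.arange(n) / (p.drift_period_s * fps))
    green = np.clip(
        p.baseline_f * (1.0 + clean)[None, :]
        + drift[None, :]
        + rng.normal(0, p.noise_sd, (n_roi, n)),
        0.0, None,
    )
    red = np.clip(
        p.red_level + drift[None, :] + rng.normal(0, p.noise_sd, (n_roi, n)), 0.0, None
    )

    w = int(round(p.step_duration_s * fps))
    t6_egg = np.zeros(n)
    t6_ovi = np.zeros(n)
    for t0, ty in zip(onsets, types):
        i0 = int(round(t0 * fps))
        target = t6_ovi if ty == "ovipositor_extrusion" else t6_egg
        target[i0 : min(n, i0 + w)] += p.step_height
    base = 1.0
    distances = {
        "t6_egg": base + t6_egg + rng.normal(0, p.distance_noise_sd, n),
        "t6_ovi": base + t6_ovi + rng.normal(0, p.distance_noise_sd, n),
        "t6_analia": np.full(n, base) + rng.normal(0, p.distance_noise_sd / 4, n),
    }
    rec = FluorescenceRecording(green=green, red=red, fps=fps)
    truth = GroundTruth(
        event_onsets_s=onsets,
        event_types=types,
        extra={"clean_dff": clean, "kernel_peak": p.amplitude_dff},
    )
    return rec, distances, truth


# ---------------------------------------------------------------------------
# Egg depth tables
# ---------------------------------------------------------------------------

#: Depth-category probabilities (P0, P0.5, P1) by substrate % agarose:
#: softer substrates take deeper eggs.
DEFAULT_DEPTH_PROBS: dict[float, tuple[float, float, float]] = {
    0.5: (0.05, 0.15, 0.80),
    1.0: (0.15, 0.25, 0.60),
    2.0: (0.50, 0.30, 0.20),
}


def simulate_egg_depths(
    depth_probs: Optional[dict[float, tuple[float, float, float]]] = None,
    eggs_per_fly_lam: float = 20.0,
    n_flies: int = 48,
    wall_prob: float = 0.1,
    drop_prob: float = 0.05,
    seed: int = 0,
) -> tuple[list[EggRecord], GroundTruth]:
    """Per-fly egg records across substrate-firmness levels.

    For each firmness level, ``n_flies`` flies lay Poisson(+1) numbers of
    eggs whose depth categories {0, 0.5, 1} follow the level's probability
    vector; location and mode are Bernoulli draws.  The ground truth stores
    the generating probabilities and the implied mean normalized depth.
    """
    probs = DEFAULT_DEPTH_PROBS if depth_probs is None else depth_probs
    for level, pv in probs.items():
        if not np.isclose(sum(pv), 1.0) or min(pv) < 0:
            raise ValueError(f"invalid depth probabilities for level {level}")
    rng = np.random.default_rng(seed)
    records: list[EggRecord] = []
    depths = np.array([0.0, 0.5, 1.0])
    for level, pv in probs.items():
        for i in range(n_flies):
            n_eggs = 1 + rng.poisson(max(eggs_per_fly_lam - 1, 0))
            cats = rng.choice(3, size=n_eggs, p=pv)
            for c in cats:
                records.append(
                    EggRecord(
                        fly_id=f"s{level}_fly{i}",
                        depth=float(depths[c]),
                        location="wall" if rng.random() < wall_prob else "substrate",
                        mode="dropped" if rng.random() < drop_prob else "burrowed",
                        substrate_pct_agarose=level,
                    )
                )
    truth = GroundTruth(
        depth_probs=dict(probs),
        mean_depth={lv: float(np.dot(depths, pv)) for lv, pv in probs.items()},
        extra={"wall_prob": wall_prob, "drop_prob": drop_prob},
    )
    return records, truth


# ---------------------------------------------------------------------------
# Feature-space motifs for the behavior-map benchmarks
# ---------------------------------------------------------------------------

def simulate_motif_features(
    n_motifs: int = 2,
    n_frames: int = 6000,
    n_features: int = 17,
    block_s: float = 3.0,
    separation: float = 6.0,
    noise_sd: float = 1.0,
    fps: float = 20.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Blockwise motif structure in feature space with known frame labels.

    Frames are organized into contiguous blocks (exponential block lengths
    with mean ``block_s``); each block draws one of ``n_motifs`` motifs whose
    feature-space centers are mutually ``separation`` standard deviations
    apart.  Returns ``(features, motif_labels)`` with labels in
    ``1..n_motifs``.
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 1, (n_motifs, n_features))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= separation / np.sqrt(2.0)  # pairwise distance ~ separation
    labels = np.empty(n_frames, dtype=np.int64)
    t = 0
    while t < n_frames:
        L = max(1, int(rng.exponential(block_s) * fps))
        labels[t : t + L] = rng.integers(1, n_motifs + 1)
        t += L
    X = centers[labels - 1] + rng.normal(0, noise_sd, (n_frames, n_features))
    return X, labels
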