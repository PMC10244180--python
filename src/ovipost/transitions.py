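"""Start-to-start transition structure of the egg-laying sequence.

The unit of analysis is the *behavior onset*: each bout start contributes one
item to a per-event :class:`StartSequence`, and consecutive onset pairs are
the start-to-start transitions tallied into a 7 x 7
:class:`TransitionMatrix`.  Transition probabilities are estimated
separately for the portion of the sequence before versus after completed egg
expulsion, and the significance of each transition is assessed against a
null distribution built from uniform shuffles of the label order within each
sequence (which preserves every event's behavioral repertoire).

Also here: the first-occurrence ordering table, the egg-expulsion-aligned
behavior time course, and per-fly progression probabilities
(bend -> burrow, burrow -> egg expulsion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ethogram import LABELS, LABEL_INDEX, BehaviorBout, Ethogram, to_bouts

N = len(LABELS)


@dataclass
class StartSequence:
    """Ordered behavior onsets for one egg-laying event.

    ``phase_split`` is the index of the egg-expulsion item, if present; items
    up to and including it form the pre-expulsion phase, items from it onward
    the post-expulsion phase (the expulsion onset is the shared boundary).
    """

    event_id: str
    items: list[tuple[str, int]]
    phase_split: Optional[int] = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [f for _, f in self.items]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("onset frames must be strictly increasing")
        eggs = [i for i, (lab, _) in enumerate(self.items) if lab == "egg_out"]
        if len(eggs) > 1:
            raise ValueError("at most one egg_out item per sequence")
        if self.phase_split is None and eggs:
            self.phase_split = eggs[0]

    def labels(self, phase: str = "all") -> list[str]:
        """Label order for a phase: 'pre', 'post' or 'all'."""
        if phase == "all":
            items = self.items
        elif phase == "pre":
            items = self.items if self.phase_split is None else self.items[: self.phase_split + 1]
        elif phase == "post":
            items = [] if self.phase_split is None else self.items[self.phase_split :]
        else:
            raise ValueError(f"phase must be 'pre', 'post' or 'all', got {phase!r}")
        return [lab for lab, _ in items]


@dataclass
class TransitionMatrix:
    """Pooled start-to-start transition counts and row-normalized probabilities.

    ``significant[i, j]`` requires both ``pvals[i, j] < alpha`` and
    ``probs[i, j] >= prob_floor``: low-probability transitions are never
    reported as significant regardless of p-value.
    """

    labels: tuple[str, ...]
    counts: np.ndarray
    probs: np.ndarray
    phase: str
    initial_distribution: np.ndarray
    pvals: Optional[np.ndarray] = None
    significant: Optional[np.ndarray] = None
    n_perm: int = 0
    alpha: float = np.nan
    prob_floor: float = np.nan

    def to_frame(self, which: str = "probs") -> pd.DataFrame:
        arr = getattr(self, which)
        return pd.DataFrame(arr, index=list(self.labels), columns=list(self.labels))

    def to_dict(self) -> dict:
        out = {
            "labels": list(self.labels),
            "phase": self.phase,
            "counts": self.counts.tolist(),
            "probs": self.probs.tolist(),
            "initial_distribution": self.initial_distribution.tolist(),
            "n_perm": self.n_perm,
        }
        if self.pvals is not None:
            out["pvals"] = self.pvals.tolist()
            out["significant"] = self.significant.tolist()
            out["alpha"] = self.alpha
            out["prob_floor"] = self.prob_floor
        return out


# ---------------------------------------------------------------------------
# Onset extraction
# ---------------------------------------------------------------------------

def extract_start_sequence(
    bouts: Sequence[BehaviorBout],
    location: Optional[np.ndarray] = None,
    min_pe_spacing: float = 0.5,
    fps: float = 20.0,
    event_id: str = "",
) -> StartSequence:
    """Turn a sorted bout list into the filtered onset sequence.

    Three filters mirror the manual scoring conventions:

    1. proboscis-extension onsets closer than ``min_pe_spacing`` (mm) to the
       previously counted extension location are dropped (requires a
       ``location`` track, ``(n_frames, 2)`` in mm; without one the filter is
       skipped with a warning recorded in the sequence provenance);
    2. proboscis-extension onsets that occur while any other behavior is
       active are dropped;
    3. a sustained abdominal bend contributes a single onset even if
       burrowing aborts and restarts inside it — guaranteed by the bout
       (run-length) representation, where one bend bout is one onset.
    """
    provenance: list[str] = []
    spacing_active = min_pe_spacing > 0 and location is not None
    if min_pe_spacing > 0 and location is None and any(b.label == "pe" for b in bouts):
        msg = "pe spacing filter skipped: no location track"
        warnings.warn(msg, stacklevel=2)
        provenance.append(msg)

    items: list[tuple[str, int]] = []
    last_pe_loc: Optional[np.ndarray] = None
    for b in bouts:
        if b.label == "pe":
            # filter (ii): pe starting while another behavior is active
            if any(o.label != "pe" and o.contains(b.start) for o in bouts):
                continue
            if spacing_active:
                loc = np.asarray(location[b.start], dtype=float)
                if last_pe_loc is not None and np.linalg.norm(loc - last_pe_loc) < min_pe_spacing:
                    continue
                last_pe_loc = loc
        items.append((b.label, b.start))
    return StartSequence(event_id=event_id, items=items, provenance=provenance)


def sequences_from_ethograms(
    ethograms: Iterable[Ethogram], min_pe_spacing: float = 0.5
) -> list[StartSequence]:
    """Convenience: bout-encode and extract onset sequences for a cohort."""
    return [
        extract_start_sequence(
            to_bouts(e),
            location=e.location_track,
            min_pe_spacing=min_pe_spacing,
            fps=e.fps,
            event_id=e.event_id,
        )
        for e in ethograms
    ]


# ---------------------------------------------------------------------------
# Transition estimation and permutation significance
# ---------------------------------------------------------------------------

def _codes(seqs: Sequence[StartSequence], phase: str) -> list[np.ndarray]:
    return [
        np.array([LABEL_INDEX[lab] for lab in s.labels(phase)], dtype=np.intp) for s in seqs
    ]


def _tally(code_arrays: Sequence[np.ndarray]) -> np.ndarray:
    counts = np.zeros(N * N, dtype=np.int64)
    for c in code_arrays:
        if c.size >= 2:
            counts += np.bincount(c[:-1] * N + c[1:], minlength=N * N)
    return counts.reshape(N, N)


def _row_normalize(counts: np.ndarray) -> np.ndarray:
    probs = counts.astype(float)
    rowsum = probs.sum(axis=1, keepdims=True)
    np.divide(probs, rowsum, out=probs, where=rowsum > 0)
    return probs


def estimate_transitions(seqs: Sequence[StartSequence], phase: str = "pre") -> TransitionMatrix:
    """Pool start-to-start transition counts over events and row-normalize.

    Self-transitions (a behavior that started, stopped and started again with
    no intervening behavior onset) are counted on the diagonal.  Rows with no
    outgoing starts are left all-zero.
    """
    if not seqs:
        raise ValueError("at least one sequence required")
    codes = _codes(seqs, phase)
    if not any(c.size for c in codes):
        raise ValueError(f"no onsets in phase {phase!r}")
    counts = _tally(codes)
    init = np.zeros(N)
    firsts = [c[0] for c in codes if c.size]
    for f in firsts:
        init[f] += 1
    init /= max(len(firsts), 1)
    return TransitionMatrix(
        labels=LABELS,
        counts=counts,
        probs=_row_normalize(counts),
        phase=phase,
        initial_distribution=init,
    )


def permutation_test(
    observed: TransitionMatrix,
    seqs: Sequence[StartSequence],
    n_perm: int = 10_000,
    alpha: float = 0.001,
    prob_floor: float = 0.04,
    seed: int = 0,
) -> TransitionMatrix:
    """One-sided permutation significance for each transition probability.

    The null shuffles the label order uniformly and independently within each
    sequence (restricted to the phase of ``observed``), preserving each
    event's label multiset and length.  For each cell,
    ``p = (1 + #{permuted prob >= observed prob}) / (1 + n_perm)`` —
    the add-one estimator, so p is never exactly 0.  A transition is flagged
    significant only if additionally its observed probability is at least
    ``prob_floor``.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    codes = _codes(seqs, observed.phase)
    concat = np.concatenate([c for c in codes if c.size]) if codes else np.empty(0, np.intp)
    seg = np.concatenate([np.full(c.size, i, dtype=np.intp) for i, c in enumerate(codes) if c.size])
    obs_probs = observed.probs
    exceed = np.zeros((N, N), dtype=np.int64)
    same_seg = seg[:-1] == seg[1:] if concat.size >= 2 else np.empty(0, bool)
    for _ in range(n_perm):
        keys = rng.random(concat.size)
        order = np.lexsort((keys, seg))  # random order within each segment
        shuf = concat[order]
        pair = shuf[:-1] * N + shuf[1:]
        counts = np.bincount(pair[same_seg], minlength=N * N).reshape(N, N)
        exceed += _row_normalize(counts) >= obs_probs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    significant = (pvals < alpha) & (obs_probs >= prob_floor)
    return TransitionMatrix(
        labels=observed.labels,
        counts=observed.counts,
        probs=obs_probs,
        phase=observed.phase,
        initial_distribution=observed.initial_distribution,
        pvals=pvals,
        significant=significant,
        n_perm=n_perm,
        alpha=alpha,
        prob_floor=prob_floor,
    )


# ---------------------------------------------------------------------------
# First-occurrence ordering, time course, progression probabilities
# ---------------------------------------------------------------------------

def first_occurrence_order(seqs: Sequence[StartSequence]) -> pd.DataFrame:
    """Fraction of events in which each behavior's first onset is k-th.

    Only events expressing all seven behaviors enter the table (events
    missing any component are excluded); each behavior's row sums to 1.
    Rows are labels; columns are ordinal positions 1..7.
    """
    table = np.zeros((N, N))
    n_used = 0
    for s in seqs:
        firsts: dict[str, int] = {}
        for lab, frame in s.items:
            firsts.setdefault(lab, frame)
        if len(firsts) < N:
            continue
        order = sorted(firsts, key=firsts.get)
        for pos, lab in enumerate(order):
            table[LABEL_INDEX[lab], pos] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no sequence expresses all behaviors")
    table /= n_used
    df = pd.DataFrame(table, index=list(LABELS), columns=np.arange(1, N + 1))
    df.attrs["n_events"] = n_used
    return df


def behavior_time_course(
    ethograms: Sequence[Ethogram], window_s: float = 60.0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Egg-expulsion-aligned fraction of events with each behavior active.

    Returns ``(times_s, fractions)`` where ``times_s`` spans
    ``[-window_s, +window_s]`` at the cohort frame rate and
    ``fractions.loc[label]`` is, at each relative time, the fraction of
    events (among those whose recording covers that time) with the behavior
    active; t = 0 is the completed-egg-expulsion frame.
    """
    anchored = [e for e in ethograms if e.egg_out_frame is not None]
    if not anchored:
        raise ValueError("no ethogram with an egg_out anchor")
    fps = anchored[0].fps
    w = int(round(window_s * fps))
    active = np.zeros((N, 2 * w + 1))
    covered = np.zeros(2 * w + 1)
    for e in anchored:
        lo = e.egg_out_frame - w
        hi = e.egg_out_frame + w + 1
        src_lo, src_hi = max(lo, 0), min(hi, e.n_frames)
        dst_lo, dst_hi = src_lo - lo, src_hi - lo
        active[:, dst_lo:dst_hi] += e.activity[src_lo:src_hi].T
        covered[dst_lo:dst_hi] += 1
    frac = np.divide(active, covered, out=np.zeros_like(active), where=covered > 0)
    times = (np.arange(-w, w + 1)) / fps
    return times, pd.DataFrame(frac, index=list(LABELS), columns=times)


_SUPPORTED_PAIRS = {("bend", "burrow"), ("burrow", "egg_out")}


def progression_probability(
    ethograms: Sequence[Ethogram],
    from_label: str,
    to_label: str,
    min_bouts: int = 3,
) -> pd.DataFrame:
    """Per-fly probability of progressing from one stage to the next.

    bend -> burrow: fraction of bend bouts during which at least one burrow
    onset occurs.  burrow -> egg_out: fraction of burrow bouts containing the
    completed-expulsion frame.  Flies with fewer than ``min_bouts`` 'from'
    bouts are excluded.
    """
    if (from_label, to_label) not in _SUPPORTED_PAIRS:
        raise ValueError(f"unsupported progression pair {(from_label, to_label)!r}")
    per_fly: dict[str, list[int]] = {}
    for e in ethograms:
        bouts = to_bouts(e)
        from_bouts = [b for b in bouts if b.label == from_label]
        if to_label == "burrow":
            onsets = [b.start for b in bouts if b.label == "burrow"]
            hits = [any(fb.start <= s < fb.end for s in onsets) for fb in from_bouts]
        else:  # burrow -> egg_out
            egg = e.egg_out_frame
            hits = [egg is not None and fb.start <= egg <= fb.end for fb in from_bouts]
        per_fly.setdefault(e.fly_id, []).extend(int(h) for h in hits)
    rows = []
    for fly, hits in sorted(per_fly.items()):
        if len(hits) < min_bouts:
            continue
        rows.append({
            "fly_id": fly,
            "n_bouts": len(hits),
            "n_progressed": int(sum(hits)),
            "probability": sum(hits) / len(hits),
        })
    return pd.DataFrame(rows, columns=["fly_id", "n_bouts", "n_progressed", "probability"])
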