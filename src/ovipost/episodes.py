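"""Burrow-episode substructure, egg-record summaries and photostimulation scoring.

A burrowing episode is one contiguous burrow bout carrying one or more
rhythmic ovipositor cycles; it either aborts or ends in egg expulsion.
Eggs are scored for depth of penetration on a {0, 0.5, 1} scale (fully
buried = 1, partial = 0.5, surface = 0), for location (substrate vs chamber
wall) and for mode (burrowed vs spontaneously dropped in midair).

The photostimulation classifier reproduces the post-expulsion scoring rules:
a fly *advances* in the sequence if no further burrowing episode begins
within a reset gap (default 65 s) of the end of the expelling episode, and
*reverts* otherwise, with the reset anchored at the onset of the last
burrowing episode preceding a burrow-free gap of that length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ethogram import Ethogram, EthogramError, to_bouts


@dataclass(frozen=True)
class BurrowEpisode:
    start: int          # frame, inclusive
    end: int            # frame, exclusive
    cycle_frames: tuple[int, ...]
    outcome: str        # 'abort' | 'expel'
    fps: float = 20.0
    fly_id: str = ""
    event_id: str = ""

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_frames)

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.fps


@dataclass(frozen=True)
class EggRecord:
    """One deposited egg: normalized depth score, location and mode."""

    fly_id: str
    depth: float                 # in {0, 0.5, 1}
    location: str = "substrate"  # 'substrate' | 'wall'
    mode: str = "burrowed"       # 'burrowed' | 'dropped'
    substrate_pct_agarose: float = 1.0

    def __post_init__(self) -> None:
        if self.depth not in (0.0, 0.5, 1.0):
            raise ValueError(f"depth must be 0, 0.5 or 1, got {self.depth}")
        if self.location not in ("substrate", "wall"):
            raise ValueError(f"bad location {self.location!r}")
        if self.mode not in ("burrowed", "dropped"):
            raise ValueError(f"bad mode {self.mode!r}")


@dataclass(frozen=True)
class StimTrial:
    """One optogenetic stimulation trial (times in seconds)."""

    light_on: float
    light_off: float
    egg_out_time: Optional[float] = None
    pulse_offsets: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.light_on < self.light_off:
            raise ValueError("light_on must precede light_off")

    @property
    def last_pulse_offset(self) -> float:
        return max(self.pulse_offsets) if self.pulse_offsets else self.light_off


@dataclass(frozen=True)
class PostExpulsionOutcome:
    category: str                       # 'advance' | 'revert'
    stop_after_egg_out_s: float         # expelling-episode end relative to egg out
    reset_time: Optional[float] = None  # onset of last burrow episode before reset
    expelled_after_stim: Optional[bool] = None


def segment_burrow_episodes(e: Ethogram) -> list[BurrowEpisode]:
    """One episode per burrow bout, with its cycles and abort/expel outcome.

    Cycle frames are partitioned among episodes; a cycle frame outside every
    burrow bout is a validation error.  An episode expels iff the completed
    egg-expulsion frame lies within it (closed interval, since expulsion is
    marked at the instant burrowing concludes).
    """
    episodes: list[BurrowEpisode] = []
    burrow_bouts = [b for b in to_bouts(e, labels=("burrow",))]
    cycles = np.asarray(e.cycle_frames, dtype=int)
    assigned = np.zeros(cycles.size, dtype=bool)
    egg = e.egg_out_frame
    for b in burrow_bouts:
        in_bout = (cycles >= b.start) & (cycles < b.end)
        assigned |= in_bout
        outcome = "expel" if (egg is not None and b.start <= egg <= b.end) else "abort"
        episodes.append(
            BurrowEpisode(
                start=b.start,
                end=b.end,
                cycle_frames=tuple(int(c) for c in cycles[in_bout]),
                outcome=outcome,
                fps=e.fps,
                fly_id=e.fly_id,
                event_id=e.event_id,
            )
        )
    if not np.all(assigned):
        bad = int(cycles[~assigned][0])
        raise EthogramError(f"cycle frame {bad} lies outside every burrow bout")
    return episodes


def burrow_cycle_stats(
    episodes: Sequence[BurrowEpisode], min_episodes: int = 2
) -> dict:
    """Cycle-count distributions, per-fly means by outcome, and r(cycles, duration).

    Per-fly means are computed separately for aborted and expelling episodes;
    a fly enters the mean for an outcome only with at least ``min_episodes``
    episodes of that outcome.  The correlation is the Pearson r between cycle
    count and episode duration pooled over all episodes.
    """
    if len(episodes) < 2:
        raise ValueError("need at least 2 episodes for the cycle/duration correlation")
    cyc = np.array([ep.n_cycles for ep in episodes], dtype=float)
    dur = np.array([ep.duration_s for ep in episodes], dtype=float)
    r, r_p = stats.pearsonr(cyc, dur)

    per_fly_rows = []
    for outcome in ("abort", "expel"):
        by_fly: dict[str, list[int]] = {}
        for ep in episodes:
            if ep.outcome == outcome:
                by_fly.setdefault(ep.fly_id, []).append(ep.n_cycles)
        for fly, counts in sorted(by_fly.items()):
            if len(counts) < min_episodes:
                continue
            per_fly_rows.append(
                {"fly_id": fly, "outcome": outcome, "n_episodes": len(counts),
                 "mean_cycles": float(np.mean(counts))}
            )
    return {
        "pooled_cycles": cyc,
        "pooled_durations_s": dur,
        "pearson_r": float(r),
        "pearson_p": float(r_p),
        "per_fly": pd.DataFrame(
            per_fly_rows, columns=["fly_id", "outcome", "n_episodes", "mean_cycles"]
        ),
    }


def egg_output_summary(
    records: Sequence[EggRecord],
    min_eggs_depth: int = 1,
    min_eggs_wall: int = 3,
    min_eggs_dropped: int = 2,
) -> pd.DataFrame:
    """Per-fly egg count, mean normalized depth, wall fraction, dropped fraction.

    Each metric applies its own minimum egg count; a fly below the minimum
    gets NaN for that metric (and is thereby excluded from cohort averages).
    """
    if not records:
        raise ValueError("empty record set")
    rows = []
    by_fly: dict[str, list[EggRecord]] = {}
    for r in records:
        by_fly.setdefault(r.fly_id, []).append(r)
    for fly, recs in sorted(by_fly.items()):
        n = len(recs)
        rows.append({
            "fly_id": fly,
            "n_eggs": n,
            "mean_depth": float(np.mean([r.depth for r in recs])) if n >= min_eggs_depth else np.nan,
            "wall_fraction": (
                sum(r.location == "wall" for r in recs) / n if n >= min_eggs_wall else np.nan
            ),
            "dropped_fraction": (
                sum(r.mode == "dropped" for r in recs) / n if n >= min_eggs_dropped else np.nan
            ),
        })
    return pd.DataFrame(rows)


def classify_drop(e: Ethogram, lookback_s: float = 5.0) -> str:
    """'dropped' if the egg emerged with no burrowing in the preceding window.

    Operationalizes a spontaneous midair drop as an expulsion with no active
    burrow frame in the ``lookback_s`` seconds before the expulsion frame.
    """
    if e.egg_out_frame is None:
        raise ValueError("ethogram has no egg_out frame")
    lo = max(0, e.egg_out_frame - int(round(lookback_s * e.fps)))
    return "burrowed" if e.column("burrow")[lo : e.egg_out_frame + 1].any() else "dropped"


def classify_post_expulsion(
    e: Ethogram,
    trial: Optional[StimTrial] = None,
    reset_gap_s: float = 65.0,
    expel_window_s: float = 4.0,
) -> PostExpulsionOutcome:
    """Advance/revert classification of the post-expulsion sequence.

    *Advance*: after the end of the expelling burrow episode, no further
    burrow onset occurs before a ``reset_gap_s`` burrow-free window has
    elapsed.  *Revert*: otherwise; the reset is then anchored at the onset of
    the last burrowing episode that precedes a ``reset_gap_s`` burrow-free
    window (end of recording counts as burrow-free).  When a
    :class:`StimTrial` is supplied, the expelled-after-stimulation flag is
    true iff the egg emerged no later than ``expel_window_s`` after the last
    light-pulse offset.
    """
    flag = None
    if trial is not None and trial.egg_out_time is not None:
        flag = bool(trial.egg_out_time <= trial.last_pulse_offset + expel_window_s)
    if e.egg_out_frame is None:
        raise ValueError("outcome classification requires an egg_out frame")

    episodes = segment_burrow_episodes(e)
    expelling = [ep for ep in episodes if ep.outcome == "expel"]
    if not expelling:
        raise EthogramError("egg_out frame lies outside every burrow episode")
    exp = expelling[0]
    gap = int(round(reset_gap_s * e.fps))
    egg = int(e.egg_out_frame)
    stop_s = (exp.end - egg) / e.fps

    later = [ep for ep in episodes if ep.start >= exp.end]
    # advance iff no burrow onset within the reset gap after the expelling episode
    if not any(ep.start < exp.end + gap for ep in later):
        return PostExpulsionOutcome("advance", stop_s, None, flag)
    # revert: anchored at the LAST episode followed by a reset_gap burrow-free
    # window (the final transition to quiescence); the end of the recording
    # counts as burrow-free
    reset_ep = later[-1]
    for ep in reversed(later):
        nxt = min((o.start for o in later if o.start >= ep.end), default=e.n_frames)
        if nxt - ep.end >= gap or nxt >= e.n_frames:
            reset_ep = ep
            break
    return PostExpulsionOutcome("revert", stop_s, reset_ep.start / e.fps, flag)
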