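"""Frame-wise multi-label ethograms of egg-laying behavior.

The egg-laying sequence of gravid *Drosophila* females is annotated frame by
frame with seven component behaviors: proboscis extension (``pe``), ``walk``,
abdominal ``bend``, substrate ``burrow``, completed egg expulsion
(``egg_out``), ``detach`` and ``groom``.  Annotations are multi-label: an
abdominal bend is maintained throughout burrowing, egg expulsion and
detachment, so a frame may carry several active behaviors at once.  The one
hard exclusion is that a fly cannot walk while burrowing.

An :class:`Ethogram` stores the frame x behavior boolean activity matrix
together with per-event metadata (frame rate, annotated burrow-cycle frames,
the egg-expulsion frame, and an optional x-y location track used by spatial
filters downstream).  :func:`to_bouts` gives the run-length (bout) view that
every downstream analysis consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

#: The seven annotated component behaviors, in canonical column order.
LABELS: tuple[str, ...] = ("pe", "walk", "bend", "burrow", "egg_out", "detach", "groom")

LABEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(LABELS)}

#: Fixed priority used to order behavior onsets that fall on the same frame
#: (highest first).  Ties are rare; the ordering is logged by callers.
ONSET_PRIORITY: tuple[str, ...] = ("egg_out", "burrow", "bend", "detach", "groom", "pe", "walk")


class EthogramError(ValueError):
    """Raised for schema or invariant violations in ethogram data."""


@dataclass(frozen=True)
class BehaviorBout:
    """A maximal contiguous run of one active behavior.

    Frames are 0-based and the interval is half-open: ``[start, end)``.
    """

    label: str
    start: int
    end: int
    fps: float = 20.0

    def __post_init__(self) -> None:
        if self.label not in LABEL_INDEX:
            raise EthogramError(f"unknown behavior label {self.label!r}")
        if not self.start < self.end:
            raise EthogramError(f"bout must have start < end, got [{self.start}, {self.end})")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.fps

    def contains(self, frame: int) -> bool:
        return self.start <= frame < self.end


@dataclass
class Ethogram:
    """Multi-label frame x behavior activity record for one egg-laying event.

    Parameters
    ----------
    activity
        Boolean array of shape ``(n_frames, 7)``; columns follow :data:`LABELS`.
    fps
        Acquisition frame rate in frames per second (video default 20 Hz).
    cycle_frames
        Frame indices of annotated burrow cycles; each must fall inside an
        active burrow frame.
    egg_out_frame
        Frame of completed egg expulsion (the t = 0 anchor of aligned
        analyses), if one occurred.
    location_track
        Optional ``(n_frames, 2)`` x-y position in mm, used by the proboscis
        extension spacing filter.
    """

    activity: np.ndarray
    fps: float = 20.0
    fly_id: str = ""
    event_id: str = ""
    cycle_frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    egg_out_frame: Optional[int] = None
    location_track: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=bool)
        if self.activity.ndim != 2 or self.activity.shape[1] != len(LABELS):
            raise EthogramError(
                f"activity must be (n_frames, {len(LABELS)}), got {self.activity.shape}"
            )
        self.cycle_frames = np.asarray(self.cycle_frames, dtype=int)
        if self.location_track is not None:
            self.location_track = np.asarray(self.location_track, dtype=float)
            if self.location_track.shape != (self.n_frames, 2):
                raise EthogramError("location_track must be (n_frames, 2)")
        self.validate()

    @property
    def n_frames(self) -> int:
        return self.activity.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.activity[:, LABEL_INDEX[label]]

    def validate(self) -> None:
        if self.fps <= 0:
            raise EthogramError(f"fps must be > 0, got {self.fps}")
        walk = self.column("walk")
        burrow = self.column("burrow")
        if np.any(walk & burrow):
            bad = int(np.flatnonzero(walk & burrow)[0])
            raise EthogramError(f"walk and burrow simultaneously active at frame {bad}")
        if self.cycle_frames.size:
            if np.any(np.diff(self.cycle_frames) <= 0):
                raise EthogramError("cycle_frames must be strictly increasing")
            inside = burrow[self.cycle_frames.clip(0, self.n_frames - 1)]
            if (
                np.any(self.cycle_frames < 0)
                or np.any(self.cycle_frames >= self.n_frames)
                or not np.all(inside)
            ):
                raise EthogramError("every cycle frame must lie inside an active burrow frame")
        if self.egg_out_frame is not None:
            f = int(self.egg_out_frame)
            if not (0 <= f < self.n_frames) or not self.column("egg_out")[f]:
                raise EthogramError(f"egg_out_frame {f} is not an active egg_out frame")

    def equals(self, other: "Ethogram") -> bool:
        """Bit-exact frame/label content equality (metadata included)."""
        return (
            self.n_frames == other.n_frames
            and np.array_equal(self.activity, other.activity)
            and self.fps == other.fps
            and self.fly_id == other.fly_id
            and self.event_id == other.event_id
            and np.array_equal(self.cycle_frames, other.cycle_frames)
            and self.egg_out_frame == other.egg_out_frame
        )

    def copy(self) -> "Ethogram":
        return replace(
            self,
            activity=self.activity.copy(),
            cycle_frames=self.cycle_frames.copy(),
            location_track=None if self.location_track is None else self.location_track.copy(),
        )


def to_bouts(e: Ethogram, labels: Optional[Sequence[str]] = None) -> list[BehaviorBout]:
    """Run-length encode an ethogram into per-label bouts.

    Bouts are returned sorted by (start frame, onset priority).  Concatenating
    the frame ranges of the returned bouts per label reproduces
    ``e.activity`` exactly (see :func:`bouts_to_activity`).
    """
    labels = tuple(labels) if labels is not None else LABELS
    bouts: list[BehaviorBout] = []
    for lab in labels:
        col = e.column(lab)
        starts, ends = _runs(col)
        bouts.extend(BehaviorBout(lab, int(s), int(t), e.fps) for s, t in zip(starts, ends))
    prio = {lab: i for i, lab in enumerate(ONSET_PRIORITY)}
    bouts.sort(key=lambda b: (b.start, prio[b.label]))
    return bouts


def bouts_to_activity(bouts: Sequence[BehaviorBout], n_frames: int) -> np.ndarray:
    """Inverse of :func:`to_bouts`: rebuild the boolean activity matrix."""
    act = np.zeros((n_frames, len(LABELS)), dtype=bool)
    for b in bouts:
        act[b.start : b.end, LABEL_INDEX[b.label]] = True
    return act


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and end (exclusive) indices of True runs."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return np.empty(0, int), np.empty(0, int)
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, m.size]
    return starts, ends


# ---------------------------------------------------------------------------
# CSV + JSON-sidecar I/O
#
# Schema: header `frame,behavior`, one row per (frame, active behavior);
# multi-label frames appear as multiple rows sharing the frame index.  Event
# metadata travels in an optional sidecar JSON next to the CSV.
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_ethogram(e: Ethogram, path: str | Path) -> Path:
    """Write an ethogram as a `frame,behavior` CSV plus a metadata sidecar."""
    path = Path(path)
    frames, labs = np.nonzero(e.activity)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("frame,behavior\n")
        for f, j in zip(frames, labs):
            fh.write(f"{f},{LABELS[j]}\n")
    meta = {
        "fly_id": e.fly_id,
        "event_id": e.event_id,
        "fps": e.fps,
        "n_frames": e.n_frames,
        "egg_out_frame": e.egg_out_frame,
        "cycle_frames": e.cycle_frames.tolist(),
    }
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
    return path


def load_ethogram(path: str | Path, fps: Optional[float] = None) -> Ethogram:
    """Load an ethogram CSV (plus sidecar metadata when present).

    ``fps`` overrides the sidecar value; without either, 20 Hz is assumed.
    Unknown behavior names and malformed rows raise :class:`EthogramError`
    naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            meta = json.load(fh)
    eff_fps = fps if fps is not None else float(meta.get("fps", 20.0))
    if eff_fps <= 0:
        raise EthogramError(f"fps must be > 0, got {eff_fps}")

    frames: list[int] = []
    labs: list[int] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != "frame,behavior":
            raise EthogramError(f"{path}: expected header 'frame,behavior', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise EthogramError(f"{path}:{lineno}: malformed row {line!r}")
            ftxt, lab = parts[0].strip(), parts[1].strip()
            try:
                f = int(ftxt)
            except ValueError:
                raise EthogramError(f"{path}:{lineno}: non-integer frame {ftxt!r}") from None
            if f < 0:
                raise EthogramError(f"{path}:{lineno}: negative frame index {f}")
            if lab not in LABEL_INDEX:
                raise EthogramError(f"{path}:{lineno}: unknown behavior {lab!r}")
            if frames and f < frames[-1]:
                raise EthogramError(f"{path}:{lineno}: non-monotone frame index {f}")
            frames.append(f)
            labs.append(LABEL_INDEX[lab])

    n_frames = int(meta.get("n_frames", (frames[-1] + 1) if frames else 0))
    act = np.zeros((n_frames, len(LABELS)), dtype=bool)
    if frames:
        act[np.array(frames), np.array(labs)] = True
    return Ethogram(
        activity=act,
        fps=eff_fps,
        fly_id=str(meta.get("fly_id", "")),
        event_id=str(meta.get("event_id", "")),
        cycle_frames=np.asarray(meta.get("cycle_frames", []), dtype=int),
        egg_out_frame=meta.get("egg_out_frame"),
    )
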