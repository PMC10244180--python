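#!/usr/bin/env python
"""Annotator-agreement analysis on degraded re-annotations (run 01 first).

Takes the simulated cohort as the reference annotation, produces a degraded
'second annotator' by jittering bout boundaries and dropping a fraction of
short bouts, expands the point-like labels to 3 frames, and scores
per-behavior and combined F1.
"""

import json
from pathlib import Path

import numpy as np

from ovipost.agreement import compare_ethograms
from ovipost.ethogram import LABELS, Ethogram, load_ethogram, to_bouts, bouts_to_activity

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 47


def degrade(e: Ethogram, rng: np.random.Generator, jitter: int = 2,
            drop_short_p: float = 0.2) -> Ethogram:
    bouts = []
    for b in to_bouts(e):
        if b.label == "egg_out":
            bouts.append(b)
            continue
        if (b.end - b.start) < 10 and rng.random() < drop_short_p:
            continue
        s = max(0, b.start + int(rng.integers(-jitter, jitter + 1)))
        t = min(e.n_frames, max(s + 1, b.end + int(rng.integers(-jitter, jitter + 1))))
        bouts.append(type(b)(b.label, s, t, b.fps))
    act = bouts_to_activity(bouts, e.n_frames)
    act[:, LABELS.index("walk")] &= ~act[:, LABELS.index("burrow")]
    return Ethogram(activity=act, fps=e.fps, egg_out_frame=e.egg_out_frame)


def main() -> None:
    rng = np.random.default_rng(SEED)
    ethos = [load_ethogram(p) for p in sorted((OUT / "cohort").glob("*.csv"))]
    f1 = {lab: [] for lab in LABELS}
    combined = []
    for e in ethos:
        rep = compare_ethograms(e, degrade(e, rng))
        for lab in LABELS:
            f1[lab].append(rep.f1[lab])
        combined.append(rep.combined_f1)
    report = {lab: float(np.mean(v)) for lab, v in f1.items()}
    report["combined_micro"] = float(np.mean(combined))
    (OUT / "agreement_f1.json").write_text(json.dumps(report, indent=1))
    for lab in LABELS:
        print(f"F1[{lab}] = {report[lab]:.3f}")
    print(f"combined (micro) F1 = {report['combined_micro']:.3f}")


if __name__ == "__main__":
    main()
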