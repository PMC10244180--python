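#!/usr/bin/env python
"""Transition structure of the simulated cohort (run 01 first).

Estimates pre- and post-expulsion start-to-start transition matrices with
permutation significance, the first-occurrence ordering table, and the
egg-out-aligned behavior time course.  Writes everything under ``results/``.
"""

import json
from pathlib import Path

from ovipost.ethogram import load_ethogram
from ovipost.transitions import (
    behavior_time_course,
    estimate_transitions,
    first_occurrence_order,
    permutation_test,
    sequences_from_ethograms,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 43


def main() -> None:
    ethos = [load_ethogram(p) for p in sorted((OUT / "cohort").glob("*.csv"))]
    seqs = sequences_from_ethograms(ethos, min_pe_spacing=0.0)

    for phase in ("pre", "post"):
        tm = estimate_transitions(seqs, phase=phase)
        tm = permutation_test(tm, seqs, n_perm=2000, alpha=0.001, prob_floor=0.04, seed=SEED)
        (OUT / f"transitions_{phase}.json").write_text(json.dumps(tm.to_dict(), indent=1))
        n_sig = int(tm.significant.sum())
        print(f"{phase}-phase: {int(tm.counts.sum())} transitions, "
              f"{n_sig} significant (p < 0.001, prob >= 0.04)")

    order = first_occurrence_order(seqs)
    order.to_csv(OUT / "first_occurrence_order.csv")
    print(f"first-occurrence table over {order.attrs['n_events']} complete events; "
          f"pe first in {order.loc['pe', 1]:.0%} of events")

    times, frac = behavior_time_course(ethos, window_s=30.0)
    frac.to_csv(OUT / "behavior_time_course.csv")
    mid = len(times) // 2
    print(f"time course written; egg_out fraction at t=0 is {frac.loc['egg_out'].iloc[mid]:.2f}")


if __name__ == "__main__":
    main()
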