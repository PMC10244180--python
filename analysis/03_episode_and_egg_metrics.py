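#!/usr/bin/env python
"""Burrow-episode substructure and egg output metrics (run 01 first).

Segments burrowing episodes from the simulated cohort, reports cycle
statistics and the cycle/duration correlation, per-fly progression
probabilities (bend -> burrow, burrow -> egg out), and per-fly egg depth
summaries across substrate firmness levels.
"""

import json
from pathlib import Path

from ovipost.episodes import burrow_cycle_stats, egg_output_summary, segment_burrow_episodes
from ovipost.ethogram import load_ethogram
from ovipost.simulate import simulate_egg_depths
from ovipost.transitions import progression_probability

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 44


def main() -> None:
    ethos = [load_ethogram(p) for p in sorted((OUT / "cohort").glob("*.csv"))]
    episodes = [ep for e in ethos for ep in segment_burrow_episodes(e)]
    stats = burrow_cycle_stats(episodes, min_episodes=2)
    stats["per_fly"].to_csv(OUT / "episode_cycle_means.csv", index=False)
    print(f"{len(episodes)} burrow episodes; "
          f"r(cycles, duration) = {stats['pearson_r']:.2f}")

    for pair in (("bend", "burrow"), ("burrow", "egg_out")):
        table = progression_probability(ethos, *pair, min_bouts=3)
        table.to_csv(OUT / f"progression_{pair[0]}_to_{pair[1]}.csv", index=False)
        if not table.empty:
            print(f"P({pair[0]} -> {pair[1]}): mean {table['probability'].mean():.2f} "
                  f"over {len(table)} flies")

    records, truth = simulate_egg_depths(n_flies=48, seed=SEED)
    summary = egg_output_summary(records)
    summary.to_csv(OUT / "egg_output_summary.csv", index=False)
    by_level = {}
    for level in truth.depth_probs:
        sub = summary[summary["fly_id"].str.startswith(f"s{level}_")]
        by_level[str(level)] = {
            "mean_depth": float(sub["mean_depth"].mean()),
            "generating_mean": truth.mean_depth[level],
        }
        print(f"substrate {level}% agarose: mean depth {by_level[str(level)]['mean_depth']:.3f} "
              f"(generator {truth.mean_depth[level]:.3f})")
    (OUT / "egg_depth_by_firmness.json").write_text(json.dumps(by_level, indent=1))


if __name__ == "__main__":
    main()
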