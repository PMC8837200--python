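"""Random-swim null model and open-field trait extraction.

Builds the synthetic step pool (a labelled stand-in for the empirical
per-frame displacement pool), fits the quartic null model of area covered as
a function of track length from 500 simulated random swims, and scores a set
of example trajectories — random swims (expected relative area ~ 0) and a
wall-following flight-style circuit (negative relative area).

Writes results/trajectory/{null_area_model.json, training_points.csv,
example_oft_summaries.csv}.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from stressg import trajectory as tj

SEED = 20260920
OUT = Path("results/trajectory")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    arena = tj.ArenaSpec()
    pool = tj.synthetic_step_pool(seed=SEED)
    print(f"step pool: {len(pool)} steps, mean {pool.distances.mean():.2f} cm, "
          f"95th pct {np.quantile(pool.distances, 0.95):.2f} cm")

    null = tj.fit_null_area_model(pool, arena, seed=SEED)
    print(f"null area model: R^2 = {null.r_squared:.3f} over track lengths "
          f"{null.fitted_range[0]:.0f}-{null.fitted_range[1]:.0f} cm")
    (OUT / "null_area_model.json").write_text(json.dumps({
        "coefficients_ascending": null.coefficients.tolist(),
        "r_squared": null.r_squared,
        "fitted_range_cm": list(null.fitted_range),
    }, indent=2))

    rng = np.random.default_rng(SEED)
    rows = []
    for k in range(12):
        L = float(rng.uniform(500, 6000))
        swim = tj.random_swim(pool, arena, L, seed=int(rng.integers(2**31)))
        s = tj.summarize_oft(swim, arena, null)
        rows.append({"trial": f"random_swim_{k}", **s.as_dict()})
    # wall-following circuit: long track, low coverage => negative relative area
    lap = [[0.5, 0.5], [19.5, 0.5], [19.5, 29.5], [0.5, 29.5]]
    circuit = tj.Trajectory.from_positions(np.array(lap * 40 + [lap[0]]), arena=arena)
    rows.append({"trial": "wall_circuit", **tj.summarize_oft(circuit, arena, null).as_dict()})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "example_oft_summaries.csv", index=False)
    print(df[["trial", "track_length", "area_covered", "relative_area",
              "time_in_middle", "freezings"]].round(3).to_string(index=False))
    swims = df[df.trial.str.startswith("random_swim")]
    print(f"\nmean relative area of fresh random swims: "
          f"{swims['relative_area'].mean():+.4f} (expected ~ 0)")
    print(f"wall circuit relative area: {df.iloc[-1]['relative_area']:+.3f} (expected < 0)")


if __name__ == "__main__":
    main()
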