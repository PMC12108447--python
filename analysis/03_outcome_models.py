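#!/usr/bin/env python
"""Univariate and multivariable outcome models on the simulated cohort.

Fits the clinical-cure model (days to TDM + regimen change, no-change
reference) and the 30-day-mortality model (SOFA, RRT, age, intra-abdominal
source, regimen change) to the study-sized cohort, and repeats the fits on a
50,000-episode cohort to show that the adjusted odds ratios recover the
generator's true effects.
"""

from pathlib import Path

import pandas as pd

from betalactam_tdm.cohort import CohortConfig, generate_cohort, to_frame
from betalactam_tdm.outcomes import study_tables

ROOT = Path(__file__).resolve().parent.parent / "results"
LARGE_N = 50_000
SEED = 1


def main() -> None:
    episodes = pd.read_csv(ROOT / "cohort" / "episodes.csv")
    for label, table in study_tables(episodes).items():
        path = ROOT / f"regression_{label}.csv"
        table.to_csv(path, index=False)
        print(f"\n== {label} (n={len(episodes)}) -> {path}")
        show = table[["predictor", "adj_or", "adj_ci_low", "adj_ci_high"]].dropna()
        print(show.round(2).to_string(index=False))

    print(f"\nparameter recovery at n={LARGE_N} (true ORs: days-to-TDM 0.92; "
          "SOFA 1.14, RRT 2.07, age 1.05, intra-abdominal 4.82, "
          "increase 0.36, decrease 0.67):")
    big = to_frame(generate_cohort(
        CohortConfig(n_episodes=LARGE_N, n_patients=round(LARGE_N * 268 / 297)),
        seed=SEED))
    for label, table in study_tables(big).items():
        show = table[["predictor", "adj_or"]].dropna()
        print(f"-- {label}: " + ", ".join(
            f"{r.predictor} {r.adj_or:.2f}" for r in show.itertuples()))


if __name__ == "__main__":
    main()
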