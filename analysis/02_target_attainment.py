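#!/usr/bin/env python
"""PK/PD target attainment for every TDM occasion of the simulated cohort.

Reads the sample table written by 01_simulate_cohort.py, reconstructs each
episode's elimination rate and steady-state profile from its peak/trough pair
(or plateau samples for continuous infusions), and writes the attainment
report: fT>MIC, fT>4xMIC and fCmin/MIC per occasion.  Prints the per-drug
medians, the service's usual summary view.
"""

from pathlib import Path

import pandas as pd

from betalactam_tdm.io import attainment_report

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    episodes = pd.read_csv(ROOT / "cohort" / "episodes.csv")
    samples = pd.read_csv(ROOT / "cohort" / "samples.csv")
    mic_by_episode = dict(zip(episodes["episode_id"], episodes["mic_mg_l"]))
    report = attainment_report(samples, mic_by_episode)
    report.to_csv(ROOT / "attainment.csv", index=False)

    ok = report[report["status"] == "ok"].merge(
        episodes[["episode_id", "drug"]], on="episode_id")
    summary = ok.groupby("drug")[
        ["fT_above_MIC_pct", "fT_above_4xMIC_pct", "fCmin_over_MIC"]
    ].median().round(1)
    print(f"attainment for {len(ok)} occasions "
          f"({(report['status'] != 'ok').sum()} flagged) -> {ROOT / 'attainment.csv'}")
    print(summary.to_string())


if __name__ == "__main__":
    main()
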