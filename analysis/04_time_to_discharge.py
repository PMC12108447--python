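#!/usr/bin/env python
"""Kaplan-Meier time-to-discharge by therapy-change group.

Excludes 30-day deaths, censors hospital stays beyond 50 days, estimates the
product-limit curve per regimen-change group, runs the all-group and
increase-vs-decrease log-rank tests, and draws the curves.  On study-sized
cohorts the group ordering (increase discharged earliest, decrease latest) is
the stable feature; the p-values fluctuate from realization to realization.
"""

from pathlib import Path

import pandas as pd

from betalactam_tdm.outcomes import km_estimate, log_rank, tte_prepare

ROOT = Path(__file__).resolve().parent.parent / "results"
COLORS = {"decrease": "tab:red", "no_change": "tab:green", "increase": "tab:blue"}


def main() -> None:
    episodes = pd.read_csv(ROOT / "cohort" / "episodes.csv")
    records = tte_prepare(episodes)

    curves = {g: km_estimate(records, g) for g in sorted(records["group"].unique())}
    pd.concat([
        pd.DataFrame({"group": g, "time": c.times, "at_risk": c.at_risk,
                      "survival": c.survival})
        for g, c in curves.items()
    ], ignore_index=True).to_csv(ROOT / "survival.csv", index=False)

    lr_all = log_rank(records)
    lr_pair = log_rank(records, ["increase", "decrease"])
    pd.DataFrame([
        {"comparison": "all_groups", "chi_square": lr_all.statistic,
         "df": lr_all.df, "p": lr_all.p_value},
        {"comparison": "increase_vs_decrease", "chi_square": lr_pair.statistic,
         "df": lr_pair.df, "p": lr_pair.p_value},
    ]).to_csv(ROOT / "logrank.csv", index=False)

    print(f"{len(records)} survivors in the TTE analysis "
          f"({records['event'].sum()} discharges, "
          f"{(~records['event']).sum()} censored at 50 d)")
    for g in ("increase", "no_change", "decrease"):
        med = records.loc[records['group'] == g, 'time'].median()
        print(f"  {g:9s} n={(records['group'] == g).sum():3d}  "
              f"median discharge {med:.0f} d")
    print(f"log-rank all groups: chi2={lr_all.statistic:.2f} p={lr_all.p_value:.4f}")
    print(f"log-rank increase vs decrease: chi2={lr_pair.statistic:.2f} "
          f"p={lr_pair.p_value:.4f}")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib unavailable; skipping the figure")
        return
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for g, c in curves.items():
        ax.step([0, *c.times], [1.0, *c.survival], where="post",
                label=g.replace("_", " "), color=COLORS.get(g))
    ax.set_xlabel("days from starting the beta-lactam")
    ax.set_ylabel("fraction remaining in hospital")
    ax.set_xlim(0, 50)
    ax.set_ylim(0, 1)
    ax.legend(title="therapy change")
    fig.tight_layout()
    fig.savefig(ROOT / "km_time_to_discharge.png", dpi=150)
    print(f"figure -> {ROOT / 'km_time_to_discharge.png'}")


if __name__ == "__main__":
    main()
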