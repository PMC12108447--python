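"""CSV schemas and the sample-table -> attainment-report path.

The episode/sample/isolate tables written by the simulator use the same
schemas a real TDM service export would: one row per episode with covariates,
regimen and outcomes; one row per timed concentration sample; one row per
isolate.  ``attainment_report`` consumes the sample table plus an episode-level
MIC and reproduces the PK/PD chain: elimination rate from the earliest
complete peak/trough pair, steady-state profile reconstruction, free-fraction
correction, fT>MIC / fT>4xMIC and fCmin/MIC.  Rows that cannot support an
estimate (e.g. trough-only occasions) are emitted with a status flag and
logged, never silently dropped.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .pk import (
    DRUG_PROFILES,
    ConcentrationSample,
    InfusionMode,
    PKError,
    Regimen,
    SampleKind,
    continuous_attainment,
    free_concentration,
    reconstruct_profile,
    target_attainment,
)

__all__ = ["attainment_report", "SAMPLE_COLUMNS", "ATTAINMENT_COLUMNS"]

log = logging.getLogger(__name__)

SAMPLE_COLUMNS = [
    "episode_id", "drug", "dose_mg", "interval_h", "infusion_h", "mode",
    "sample_kind", "time_after_dose_start_h", "total_conc_mg_L",
]

ATTAINMENT_COLUMNS = [
    "episode_id", "occasion", "ke_per_h", "half_life_h", "fCmax", "fCmin",
    "fT_above_MIC_pct", "fT_above_4xMIC_pct", "fCmin_over_MIC", "status",
]


def _pair(peaks: pd.DataFrame, troughs: pd.DataFrame):
    """Earliest complete peak/trough pair (tie-break: earliest peak)."""
    for _, pk_row in peaks.sort_values("time_after_dose_start_h").iterrows():
        later = troughs[
            troughs["time_after_dose_start_h"] > pk_row["time_after_dose_start_h"]
        ]
        if len(later):
            return pk_row, later.sort_values("time_after_dose_start_h").iloc[0]
    return None, None


def attainment_report(
    samples: pd.DataFrame, mic_by_episode: Mapping[int, float]
) -> pd.DataFrame:
    """One attainment row per TDM occasion from a sample table.

    ``mic_by_episode`` maps episode_id to the resolved effective MIC (mg/L).
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise KeyError(f"sample table missing columns: {missing}")
    rows = []
    for episode_id, grp in samples.groupby("episode_id", sort=True):
        first = grp.iloc[0]
        drug = str(first["drug"])
        base = {"episode_id": episode_id, "occasion": 1}
        nan_metrics = dict.fromkeys(ATTAINMENT_COLUMNS[2:9], np.nan)
        mic = mic_by_episode.get(episode_id)
        if mic is None or not mic > 0:
            log.warning("episode %s: no resolvable MIC; row flagged", episode_id)
            rows.append({**base, **nan_metrics, "status": "unresolvable_mic"})
            continue
        if drug not in DRUG_PROFILES:
            log.warning("episode %s: unknown drug %r; row flagged", episode_id, drug)
            rows.append({**base, **nan_metrics, "status": f"unknown_drug:{drug}"})
            continue
        profile = DRUG_PROFILES[drug]
        mode = InfusionMode(str(first["mode"]))
        regimen = Regimen(
            drug, float(first["dose_mg"]), float(first["interval_h"]),
            float(first["infusion_h"]), mode,
        )
        if mode is InfusionMode.CONTINUOUS:
            randoms = grp[grp["sample_kind"] == "random"]
            if len(randoms) == 0:
                log.warning("episode %s: continuous infusion without random "
                            "samples; row flagged", episode_id)
                rows.append({**base, **nan_metrics, "status": "no_random_samples"})
                continue
            conc = [
                ConcentrationSample(float(r.time_after_dose_start_h),
                                    float(r.total_conc_mg_L), SampleKind.RANDOM)
                for r in randoms.itertuples()
            ]
            att = continuous_attainment(conc, profile, mic)
            fcss = att.fcmin_over_mic * mic
            rows.append({
                **base, "ke_per_h": np.nan, "half_life_h": np.nan,
                "fCmax": fcss, "fCmin": fcss,
                "fT_above_MIC_pct": att.ft_above[1],
                "fT_above_4xMIC_pct": att.ft_above[4],
                "fCmin_over_MIC": att.fcmin_over_mic, "status": "ok",
            })
            continue
        peaks = grp[grp["sample_kind"] == "peak"]
        troughs = grp[grp["sample_kind"] == "trough"]
        pk_row, tr_row = _pair(peaks, troughs)
        if pk_row is None:
            log.warning("episode %s: no complete peak/trough pair "
                        "(peaks=%d, troughs=%d); row flagged",
                        episode_id, len(peaks), len(troughs))
            rows.append({**base, **nan_metrics, "status": "unresolvable_pair"})
            continue
        peak = ConcentrationSample(float(pk_row["time_after_dose_start_h"]),
                                   float(pk_row["total_conc_mg_L"]), SampleKind.PEAK)
        trough = ConcentrationSample(float(tr_row["time_after_dose_start_h"]),
                                     float(tr_row["total_conc_mg_L"]), SampleKind.TROUGH)
        try:
            est = reconstruct_profile(regimen, peak, trough)
        except PKError as exc:
            log.warning("episode %s: %s; row flagged", episode_id, exc)
            rows.append({**base, **nan_metrics, "status": f"pk_error:{exc}"})
            continue
        att = target_attainment(est, regimen, profile, mic)
        rows.append({
            **base,
            "ke_per_h": est.ke_per_h,
            "half_life_h": est.half_life_h,
            "fCmax": free_concentration(est.cmax_ss_total, profile),
            "fCmin": free_concentration(est.cmin_ss_total, profile),
            "fT_above_MIC_pct": att.ft_above[1],
            "fT_above_4xMIC_pct": att.ft_above[4],
            "fCmin_over_MIC": att.fcmin_over_mic,
            "status": "ok",
        })
    out = pd.DataFrame(rows, columns=ATTAINMENT_COLUMNS)
    n_bad = int((out["status"] != "ok").sum())
    log.info("attainment report: %d occasions, %d flagged", len(out), n_bad)
    return out
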