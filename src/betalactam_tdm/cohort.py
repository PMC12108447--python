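"""Synthetic ICU beta-lactam TDM cohort generator.

Emulates the statistical structure of an active beta-lactam TDM service in a
mixed ICU: episode-level covariates drawn from the cohort's printed marginals
(age 56 +/- 17 y, weight 82 +/- 32 kg, 57% male, 14% RRT, SOFA 6 +/- 4,
creatinine 1.26 +/- 1.14 mg/dL, lung-dominant infection sources, a
cefepime-dominant drug mix, 91% intermittent infusions), a log-normal
time-to-first-TDM process (median 2.7 d, IQR 1.7-4.7), patient-specific
one-compartment PK truth with renal-function and RRT scaling, forward-simulated
peak/trough samples with assay noise, MIC context with a breakpoint fallback,
and a clinician-style adjustment step that runs the actual recommendation
rules (stochastic 1-4x MIC target choice) to produce the
increase / no-change / decrease therapy groups.

Outcomes are then generated from logistic models whose true effects are the
adjusted odds ratios the analysis stage is meant to recover, with intercepts
calibrated so the marginal clinical-cure and 30-day-mortality proportions hit
their targets (75% and 20%).  Length of stay is generated for survivors only,
log-normal with group-ordered medians (increase < no change < decrease) and an
overall median of 22 d, censored at 50 d in the time-to-event stage.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import adjust, mic as mic_mod, pk as pk_mod
from .adjust import ChangeDirection, classify_change, recommend_regimen
from .mic import DEFAULT_BREAKPOINTS, EffectiveMIC, IsolateRecord, MICProvenance, MSSA, effective_mic
from .pk import (
    DRUG_PROFILES,
    ConcentrationSample,
    InfusionMode,
    PKEstimate,
    Regimen,
    SampleKind,
    concentration_at,
    continuous_attainment,
    predict_steady_state,
    reconstruct_profile,
    target_attainment,
)

__all__ = [
    "CohortConfig",
    "InfectionEpisode",
    "generate_cohort",
    "assign_outcomes",
    "calibrate_intercepts",
    "fit_lognormal_quantiles",
    "to_frame",
    "samples_frame",
    "isolates_frame",
]


def fit_lognormal_quantiles(q25: float, q50: float, q75: float) -> tuple[float, float]:
    """Least-squares (mu, sigma) of a log-normal hitting three printed
    quartiles.  The quartile triple is generally not exactly log-normal
    (the IQR is asymmetric around the median), so the fit minimises the
    squared log-scale quantile residuals."""
    z75 = special.ndtri(0.75)
    logs = np.log([q25, q50, q75])
    mu = logs.mean()
    sigma = (logs[2] - logs[0]) / (2.0 * z75)
    return float(mu), float(sigma)


_TDM_MU, _TDM_SIGMA = fit_lognormal_quantiles(1.7, 2.7, 4.7)

#: Population-typical clearance (L/h at reference creatinine clearance
#: 100 mL/min, or non-renal route) and volume (L at 70 kg) per drug.
DRUG_POPULATION_PK: Mapping[str, tuple[float, float]] = {
    "ampicillin": (11.0, 20.0),
    "aztreonam": (5.5, 18.0),
    "cefazolin": (4.5, 12.0),
    "cefepime": (7.5, 20.0),
    "ceftriaxone": (1.2, 11.0),
    "meropenem": (12.0, 22.0),
    "oxacillin": (18.0, 25.0),
    "piperacillin": (12.0, 20.0),
}

#: Empiric starting regimen (dose mg, interval h) for normal and impaired
#: (RRT or CrCl < 30 mL/min) renal function.
INITIAL_REGIMENS: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "ampicillin": ((2000, 6), (2000, 8)),
    "aztreonam": ((2000, 8), (1000, 12)),
    "cefazolin": ((2000, 8), (1000, 8)),
    "cefepime": ((2000, 8), (1000, 12)),
    "ceftriaxone": ((2000, 24), (2000, 24)),
    "meropenem": ((1000, 8), (500, 12)),
    "oxacillin": ((2000, 6), (2000, 6)),
    "piperacillin": ((4000, 6), (3000, 8)),
}

#: Extended-infusion duration per drug (only drugs with a long-infusion menu).
EXTENDED_INFUSION_H: Mapping[str, float] = {
    "ampicillin": 4.0,
    "aztreonam": 4.0,
    "cefepime": 4.0,
    "meropenem": 3.0,
    "piperacillin": 4.0,
}

#: Per-drug organism mix (plausible pathogen spectra) and per-organism
#: median MIC (mg/L) on the doubling-dilution grid.
ORGANISM_MIX: Mapping[str, tuple[tuple[str, float], ...]] = {
    "cefepime": (("Pseudomonas aeruginosa", 0.45), ("Escherichia coli", 0.17),
                 ("Klebsiella pneumoniae", 0.14), ("Enterobacter cloacae", 0.10),
                 ("Proteus mirabilis", 0.07), ("Serratia marcescens", 0.07)),
    "meropenem": (("Pseudomonas aeruginosa", 0.45), ("Escherichia coli", 0.17),
                  ("Klebsiella pneumoniae", 0.14), ("Enterobacter cloacae", 0.10),
                  ("Proteus mirabilis", 0.07), ("Serratia marcescens", 0.07)),
    "piperacillin": (("Pseudomonas aeruginosa", 0.45), ("Escherichia coli", 0.17),
                     ("Klebsiella pneumoniae", 0.14), ("Enterobacter cloacae", 0.10),
                     ("Proteus mirabilis", 0.07), ("Serratia marcescens", 0.07)),
    "aztreonam": (("Pseudomonas aeruginosa", 0.50), ("Escherichia coli", 0.30),
                  ("Klebsiella pneumoniae", 0.20)),
    "ceftriaxone": (("Escherichia coli", 0.40), ("Klebsiella pneumoniae", 0.30),
                    ("Proteus mirabilis", 0.15), ("Serratia marcescens", 0.15)),
    "cefazolin": (("Escherichia coli", 0.35), ("Klebsiella pneumoniae", 0.25),
                  (MSSA, 0.25), ("Proteus mirabilis", 0.15)),
    "ampicillin": (("Escherichia coli", 0.50), ("Proteus mirabilis", 0.20),
                   ("Enterococcus faecalis", 0.30)),
    "oxacillin": ((MSSA, 1.0),),
}

ORGANISM_MEDIAN_MIC: Mapping[str, float] = {
    "Pseudomonas aeruginosa": 2.0,
    "Escherichia coli": 1.0,
    "Klebsiella pneumoniae": 1.0,
    "Enterobacter cloacae": 1.0,
    "Proteus mirabilis": 1.0,
    "Serratia marcescens": 1.0,
    "Enterococcus faecalis": 1.0,
    MSSA: 2.0,
}

#: Suspected causative pathogen used for the breakpoint fallback when no
#: organism is isolated, per drug.
SUSPECTED_PATHOGEN: Mapping[str, str] = {
    "cefepime": "Pseudomonas aeruginosa",
    "meropenem": "Pseudomonas aeruginosa",
    "piperacillin": "Pseudomonas aeruginosa",
    "aztreonam": "Pseudomonas aeruginosa",
    "ceftriaxone": "Escherichia coli",
    "cefazolin": "Escherichia coli",
    "ampicillin": "Escherichia coli",
    "oxacillin": MSSA,
}


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_episodes: int = 297
    n_patients: int = 268

    # covariates
    age_mean: float = 56.0
    age_sd: float = 17.0
    age_min: float = 18.0
    weight_mean: float = 82.0
    weight_sd: float = 32.0
    weight_min: float = 30.0
    p_male: float = 0.57
    p_rrt: float = 0.14
    sofa_mean: float = 6.0
    sofa_sd: float = 4.0
    scr_mean: float = 1.26
    scr_sd: float = 1.14
    scr_min: float = 0.2
    severity_loading: float = 0.3  # shared latent coupling SOFA <-> RRT

    source_probs: tuple[tuple[str, float], ...] = (
        ("lung", 0.44), ("bacteremia", 0.17), ("skin_soft_tissue", 0.09),
        ("intra_abdominal", 0.07), ("urinary", 0.06), ("bone_joint", 0.05),
        ("endocarditis", 0.04), ("other", 0.08),
    )
    drug_probs: tuple[tuple[str, float], ...] = (
        ("cefepime", 0.45), ("meropenem", 0.20), ("piperacillin", 0.12),
        ("ceftriaxone", 0.07), ("cefazolin", 0.06), ("ampicillin", 0.04),
        ("oxacillin", 0.03), ("aztreonam", 0.03),
    )
    p_intermittent: float = 0.91
    p_extended: float = 0.07
    p_continuous: float = 0.02

    # sampling-time process (log-normal days, LS fit to median 2.7, IQR 1.7-4.7)
    tdm_log_mu: float = _TDM_MU
    tdm_log_sigma: float = _TDM_SIGMA

    # PK truth
    omega_cl: float = 0.35       # between-patient lognormal SD on clearance
    omega_v: float = 0.25        # and on volume
    rrt_cl_factor: float = 0.35  # clearance multiplier under RRT
    crcl_ref: float = 100.0      # mL/min reference for clearance scaling
    cl_crcl_exponent: float = 0.75
    assay_cv: float = 0.10       # multiplicative sampling/assay noise

    # MIC context
    p_breakpoint_mic: float = 0.27  # no-growth episodes using a breakpoint

    # clinician adjustment behaviour
    target_multiplier_probs: tuple[tuple[int, float], ...] = (
        (1, 0.55), (2, 0.10), (3, 0.05), (4, 0.30),
    )
    p_act_on_subtarget: float = 0.88
    deescalate_fcmin_threshold: float = 4.0
    p_deescalate: float = 0.80

    # outcome models: true log-odds (natural logs of the target aORs)
    cure_coef_days_to_tdm: float = math.log(0.92)
    cure_coef_increase: float = math.log(1.17)
    cure_coef_decrease: float = math.log(1.25)
    mort_coef_sofa: float = math.log(1.14)
    mort_coef_rrt: float = math.log(2.07)
    mort_coef_age: float = math.log(1.05)
    mort_coef_intra_abdominal: float = math.log(4.82)
    mort_coef_increase: float = math.log(0.36)
    mort_coef_decrease: float = math.log(0.67)
    #: intercepts calibrated with calibrate_intercepts() (targets 75% / 20%)
    alpha_cure: float = 1.3139
    alpha_mort: float = -5.1019

    # length-of-stay model (survivors): log-normal, group-offset medians
    los_median_days: float = 22.0
    los_sigma: float = 0.80
    los_log_offset_increase: float = -0.25
    los_log_offset_decrease: float = 0.25
    censor_horizon_days: float = 50.0

    seed: int | None = None

    def validate(self) -> None:
        for name in ("age_sd", "weight_sd", "sofa_sd", "scr_sd", "omega_cl",
                     "omega_v", "assay_cv", "tdm_log_sigma", "los_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_episodes < self.n_patients:
            raise ValueError("n_episodes must be >= n_patients")
        for label, probs in (("source_probs", self.source_probs),
                             ("drug_probs", self.drug_probs),
                             ("target_multiplier_probs", self.target_multiplier_probs)):
            total = sum(p for _, p in probs)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{label} must sum to 1, got {total}")
            if any(p < 0 for _, p in probs):
                raise ValueError(f"{label} has negative entries")
        mode_total = self.p_intermittent + self.p_extended + self.p_continuous
        if abs(mode_total - 1.0) > 1e-6:
            raise ValueError(f"infusion-mode probabilities must sum to 1, got {mode_total}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        kwargs = dict(d)
        for key in ("source_probs", "drug_probs", "target_multiplier_probs"):
            if key in kwargs and isinstance(kwargs[key], (list, dict)):
                items = kwargs[key].items() if isinstance(kwargs[key], dict) else kwargs[key]
                kwargs[key] = tuple((k, v) for k, v in items)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class InfectionEpisode:
    """One infection treated with one beta-lactam, with its full TDM context."""

    episode_id: int
    patient_id: int
    age: float
    weight_kg: float
    male: bool
    scr_mg_dl: float
    sofa: int
    rrt: bool
    source: str
    drug: str
    mode: InfusionMode
    cl_true_l_h: float
    v_true_l: float
    regimen_initial: Regimen
    samples: tuple[ConcentrationSample, ...]
    organism: str
    mic: EffectiveMIC
    days_to_tdm: float
    pk_estimate: PKEstimate | None
    ft_above_mic_pct: float
    ft_above_4mic_pct: float
    fcmin_over_mic: float
    target_multiplier: int
    regimen_post: Regimen
    change_group: str
    ordinal_code: int
    best_effort: bool
    clinical_cure: bool | None = None
    mortality_30d: bool | None = None
    los_days: float | None = None
    censored: bool | None = None


def _choice(rng: np.random.Generator, items: Sequence[tuple], n: int) -> np.ndarray:
    keys = [k for k, _ in items]
    probs = np.array([p for _, p in items], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(np.array(keys, dtype=object), size=n, p=probs)


def _truncated_normal(rng, mean, sd, low, size) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = out < low
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.maximum(out, low)


def _cockcroft_gault(age, weight, scr, male) -> np.ndarray:
    crcl = (140.0 - age) * weight / (72.0 * scr)
    crcl = np.where(male, crcl, 0.85 * crcl)
    return np.clip(crcl, 5.0, 160.0)


def _mic_for(rng: np.random.Generator, drug: str, organism: str,
             table: mic_mod.BreakpointTable) -> float:
    """Doubling-dilution MIC around the organism's median, capped at the
    susceptible breakpoint where one exists (resistant infections were not
    part of the service)."""
    median = ORGANISM_MEDIAN_MIC[organism]
    step = rng.choice([-2, -1, 0, 1, 2], p=[0.15, 0.25, 0.30, 0.20, 0.10])
    value = median * 2.0 ** step
    bp = table.lookup(drug, organism)
    if bp is not None:
        value = min(value, bp)
    return value


def _simulate_samples(
    rng: np.random.Generator,
    regimen: Regimen,
    pk_true: PKEstimate,
    cv: float,
) -> tuple[ConcentrationSample, ConcentrationSample]:
    """Noisy peak (about 1 h post-infusion) and trough (just before the next
    dose) drawn from the true steady-state profile."""
    t_peak = regimen.infusion_h + rng.uniform(0.75, 1.25)
    t_trough = regimen.interval_h - rng.uniform(0.1, 0.5)
    c_peak = concentration_at(pk_true, regimen, t_peak) * rng.lognormal(0.0, cv)
    c_trough = concentration_at(pk_true, regimen, t_trough) * rng.lognormal(0.0, cv)
    peak = ConcentrationSample(t_peak, max(c_peak, 1e-6), SampleKind.PEAK)
    trough = ConcentrationSample(t_trough, max(c_trough, 1e-6), SampleKind.TROUGH)
    return peak, trough


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
    include_outcomes: bool = True,
) -> list[InfectionEpisode]:
    """Generate a full synthetic cohort; deterministic given the seed.

    ``seed`` overrides ``config.seed``; one of the two must be given.
    """
    config = config or CohortConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is mandatory: set config.seed or pass seed=")
    rng = np.random.default_rng(seed)
    n = config.n_episodes
    n_pat = config.n_patients

    # patient-level covariates, then episode -> patient map (the surplus
    # episodes are second infections of randomly chosen patients)
    p_age = _truncated_normal(rng, config.age_mean, config.age_sd, config.age_min, n_pat)
    p_weight = _truncated_normal(rng, config.weight_mean, config.weight_sd,
                                 config.weight_min, n_pat)
    p_male = rng.random(n_pat) < config.p_male
    patient_of = np.concatenate([
        np.arange(n_pat), rng.integers(0, n_pat, size=n - n_pat)
    ])[:n]
    age = p_age[patient_of]
    weight = p_weight[patient_of]
    male = p_male[patient_of]

    # episode-level severity with a shared latent coupling SOFA and RRT
    lam = config.severity_loading
    z = rng.normal(size=n)
    sofa_noise = rng.normal(size=n)
    sofa_raw = config.sofa_mean + config.sofa_sd * (
        lam * z + math.sqrt(max(0.0, 1 - lam**2)) * sofa_noise
    )
    sofa = np.maximum(np.rint(sofa_raw), 0).astype(int)
    rrt_latent = lam * z + math.sqrt(max(0.0, 1 - lam**2)) * rng.normal(size=n)
    rrt = rrt_latent < special.ndtri(config.p_rrt)
    scr = _truncated_normal(rng, config.scr_mean, config.scr_sd, config.scr_min, n)
    source = _choice(rng, config.source_probs, n)
    drug = _choice(rng, config.drug_probs, n)
    mode_u = rng.random(n)
    crcl = _cockcroft_gault(age, weight, scr, male)
    days_to_tdm = np.exp(rng.normal(config.tdm_log_mu, config.tdm_log_sigma, size=n))

    # PK truth: clearance scales with renal function (or the RRT factor),
    # volume with weight, both with lognormal between-patient variability
    eta_cl = rng.normal(0.0, config.omega_cl, size=n)
    eta_v = rng.normal(0.0, config.omega_v, size=n)
    mult_probs = config.target_multiplier_probs
    target_h = _choice(rng, mult_probs, n).astype(int)
    # non-intermittent modes are only available for drugs with a long-infusion
    # menu; inflate their conditional probability so the cohort-wide
    # intermittent fraction matches p_intermittent
    eligible_mass = sum(p for drg, p in config.drug_probs if drg in EXTENDED_INFUSION_H)
    mode_scale = 1.0 / eligible_mass if eligible_mass > 0 else 0.0

    episodes: list[InfectionEpisode] = []
    for i in range(n):
        d = str(drug[i])
        profile = DRUG_PROFILES[d]
        cl_typ, v_typ = DRUG_POPULATION_PK[d]
        if rrt[i]:
            cl_true = cl_typ * config.rrt_cl_factor * math.exp(eta_cl[i])
        else:
            cl_true = (
                cl_typ
                * (crcl[i] / config.crcl_ref) ** config.cl_crcl_exponent
                * math.exp(eta_cl[i])
            )
        v_true = v_typ * (weight[i] / 70.0) * math.exp(eta_v[i])

        impaired = rrt[i] or crcl[i] < 30.0
        dose0, tau0 = INITIAL_REGIMENS[d][1 if impaired else 0]
        if d in EXTENDED_INFUSION_H and mode_u[i] >= 1.0 - (
            config.p_extended + config.p_continuous
        ) * mode_scale:
            if mode_u[i] < 1.0 - config.p_continuous * mode_scale:
                mode = InfusionMode.EXTENDED
                regimen0 = Regimen(d, dose0, tau0, EXTENDED_INFUSION_H[d], mode)
            else:
                mode = InfusionMode.CONTINUOUS
                daily = dose0 * 24.0 / tau0
                regimen0 = Regimen(d, daily, 24.0, 24.0, mode)
        else:
            mode = InfusionMode.INTERMITTENT
            regimen0 = Regimen(d, dose0, tau0, 0.5, mode)

        # MIC context
        organism = str(_choice(rng, ORGANISM_MIX[d], 1)[0])
        if rng.random() < config.p_breakpoint_mic:
            suspected = SUSPECTED_PATHOGEN[d]
            eff_mic = effective_mic([], d, suspected)
            organism = suspected
            isolate_mic = None
        else:
            isolate_mic = _mic_for(rng, d, organism, DEFAULT_BREAKPOINTS)
            eff_mic = effective_mic(
                [IsolateRecord(organism, isolate_mic)], d, organism
            )

        pk_true = predict_steady_state(cl_true, v_true, regimen0)

        if mode is InfusionMode.CONTINUOUS:
            n_samp = int(rng.integers(1, 3))
            samples = tuple(
                ConcentrationSample(
                    float(rng.uniform(0.0, 24.0)),
                    max(pk_true.cmax_ss_total * rng.lognormal(0.0, config.assay_cv), 1e-6),
                    SampleKind.RANDOM,
                )
                for _ in range(n_samp)
            )
            att = continuous_attainment(samples, profile, eff_mic.value_mg_l)
            pk_hat = None
        else:
            for _attempt in range(50):
                peak, trough = _simulate_samples(rng, regimen0, pk_true, config.assay_cv)
                try:
                    pk_hat = reconstruct_profile(regimen0, peak, trough)
                    break
                except pk_mod.PKError:
                    continue
            else:  # pragma: no cover - essentially unreachable
                raise RuntimeError("could not simulate a resolvable peak/trough pair")
            samples = (peak, trough)
            att = target_attainment(pk_hat, regimen0, profile, eff_mic.value_mg_l)

        # clinician decision: stochastic 1-4x target; escalate when the target
        # is missed, consider de-escalation when the trough is far above it
        h = int(target_h[i])
        group = ChangeDirection.NO_CHANGE
        regimen_post = regimen0
        best_effort = False
        if mode is InfusionMode.CONTINUOUS:
            free_css_over_mic = att.fcmin_over_mic
            if att.ft_above[h] < 100.0 and rng.random() < config.p_act_on_subtarget:
                daily = round(regimen0.dose_mg * 1.5 / 500.0) * 500.0
                regimen_post = replace(regimen0, dose_mg=daily)
            elif (
                free_css_over_mic > config.deescalate_fcmin_threshold
                and rng.random() < config.p_deescalate
            ):
                daily = max(round(regimen0.dose_mg * 2 / 3 / 500.0) * 500.0, 500.0)
                regimen_post = replace(regimen0, dose_mg=daily)
            cls = classify_change(regimen0, regimen_post)
            group = cls.ordinal_code
        else:
            if att.ft_above[h] < 100.0:
                if rng.random() < config.p_act_on_subtarget:
                    rec = recommend_regimen(
                        pk_hat, profile, eff_mic, target_multiplier=h, current=regimen0
                    )
                    regimen_post = rec.regimen
                    best_effort = rec.best_effort
            elif (
                att.fcmin_over_mic > config.deescalate_fcmin_threshold
                and rng.random() < config.p_deescalate
            ):
                rec = recommend_regimen(
                    pk_hat, profile, eff_mic, target_multiplier=h, current=regimen0
                )
                regimen_post = rec.regimen
            cls = classify_change(
                regimen0, regimen_post, pk=pk_hat, drug=profile,
                mic_mg_l=eff_mic.value_mg_l, target_multiplier=h,
            )
            group = cls.ordinal_code

        episodes.append(InfectionEpisode(
            episode_id=i,
            patient_id=int(patient_of[i]),
            age=float(age[i]),
            weight_kg=float(weight[i]),
            male=bool(male[i]),
            scr_mg_dl=float(scr[i]),
            sofa=int(sofa[i]),
            rrt=bool(rrt[i]),
            source=str(source[i]),
            drug=d,
            mode=mode,
            cl_true_l_h=cl_true,
            v_true_l=v_true,
            regimen_initial=regimen0,
            samples=samples,
            organism=organism,
            mic=eff_mic,
            days_to_tdm=float(days_to_tdm[i]),
            pk_estimate=pk_hat,
            ft_above_mic_pct=att.ft_above[1],
            ft_above_4mic_pct=att.ft_above[4],
            fcmin_over_mic=att.fcmin_over_mic,
            target_multiplier=h,
            regimen_post=regimen_post,
            change_group=group.label,
            ordinal_code=int(group),
            best_effort=best_effort,
        ))

    if include_outcomes:
        assign_outcomes(episodes, config, rng)
    return episodes


def assign_outcomes(
    episodes: Sequence[InfectionEpisode],
    config: CohortConfig,
    rng: np.random.Generator,
) -> Sequence[InfectionEpisode]:
    """Draw clinical cure, 30-day mortality and (survivors only) length of
    stay from the configured true-effect models, in place."""
    for ep in episodes:
        if ep.change_group is None:
            raise ValueError(f"episode {ep.episode_id} has no change group")
    inc = np.array([ep.change_group == "increase" for ep in episodes], dtype=float)
    dec = np.array([ep.change_group == "decrease" for ep in episodes], dtype=float)
    days = np.array([ep.days_to_tdm for ep in episodes])
    sofa = np.array([ep.sofa for ep in episodes], dtype=float)
    rrt = np.array([ep.rrt for ep in episodes], dtype=float)
    age = np.array([ep.age for ep in episodes])
    intra = np.array([ep.source == "intra_abdominal" for ep in episodes], dtype=float)

    lp_cure = (
        config.alpha_cure
        + config.cure_coef_days_to_tdm * days
        + config.cure_coef_increase * inc
        + config.cure_coef_decrease * dec
    )
    lp_mort = (
        config.alpha_mort
        + config.mort_coef_sofa * sofa
        + config.mort_coef_rrt * rrt
        + config.mort_coef_age * age
        + config.mort_coef_intra_abdominal * intra
        + config.mort_coef_increase * inc
        + config.mort_coef_decrease * dec
    )
    cure = rng.random(len(episodes)) < special.expit(lp_cure)
    mort = rng.random(len(episodes)) < special.expit(lp_mort)

    offset = {
        "increase": config.los_log_offset_increase,
        "decrease": config.los_log_offset_decrease,
        "no_change": 0.0,
    }
    for i, ep in enumerate(episodes):
        ep.clinical_cure = bool(cure[i])
        ep.mortality_30d = bool(mort[i])
        if ep.mortality_30d:
            ep.los_days = None
            ep.censored = None
        else:
            mu = math.log(config.los_median_days) + offset[ep.change_group]
            ep.los_days = float(np.exp(rng.normal(mu, config.los_sigma)))
            ep.censored = ep.los_days > config.censor_horizon_days
    return episodes


def calibrate_intercepts(
    config: CohortConfig | None = None,
    target_cure: float = 0.75,
    target_mortality: float = 0.20,
    n: int = 200_000,
    seed: int = 202101,
) -> tuple[float, float]:
    """Calibrate the outcome-model intercepts to marginal targets.

    Simulates the covariate / change-group distribution once at size ``n``
    (fixed seed), then solves  mean(expit(alpha + lp)) = target  for each
    outcome by monotone root finding.  Returns (alpha_cure, alpha_mort).
    """
    if not (0.0 < target_cure < 1.0 and 0.0 < target_mortality < 1.0):
        raise ValueError("targets must lie in (0, 1)")
    config = config or CohortConfig()
    sim_cfg = replace(config, n_episodes=n, n_patients=max(n * 268 // 297, 1))
    episodes = generate_cohort(sim_cfg, seed=seed, include_outcomes=False)

    inc = np.array([ep.change_group == "increase" for ep in episodes], dtype=float)
    dec = np.array([ep.change_group == "decrease" for ep in episodes], dtype=float)
    days = np.array([ep.days_to_tdm for ep in episodes])
    sofa = np.array([ep.sofa for ep in episodes], dtype=float)
    rrt = np.array([ep.rrt for ep in episodes], dtype=float)
    age = np.array([ep.age for ep in episodes])
    intra = np.array([ep.source == "intra_abdominal" for ep in episodes], dtype=float)

    lp_cure = (
        config.cure_coef_days_to_tdm * days
        + config.cure_coef_increase * inc
        + config.cure_coef_decrease * dec
    )
    lp_mort = (
        config.mort_coef_sofa * sofa
        + config.mort_coef_rrt * rrt
        + config.mort_coef_age * age
        + config.mort_coef_intra_abdominal * intra
        + config.mort_coef_increase * inc
        + config.mort_coef_decrease * dec
    )

    def solve(lp: np.ndarray, target: float) -> float:
        def gap(alpha: float) -> float:
            return float(special.expit(alpha + lp).mean() - target)

        lo, hi = -40.0, 40.0
        if gap(lo) > 0 or gap(hi) < 0:
            raise ValueError(
                f"target {target} unattainable given the coefficient block"
            )
        return float(optimize.brentq(gap, lo, hi, xtol=1e-10))

    return solve(lp_cure, target_cure), solve(lp_mort, target_mortality)


# ---------------------------------------------------------------------------
# Tabular views (the same CSV schemas the real-data path reads)


def to_frame(episodes: Sequence[InfectionEpisode]) -> pd.DataFrame:
    """Flat episode table with the analysis columns."""
    rows = []
    for ep in episodes:
        rows.append({
            "episode_id": ep.episode_id,
            "patient_id": ep.patient_id,
            "age": ep.age,
            "weight_kg": ep.weight_kg,
            "male": ep.male,
            "scr_mg_dl": ep.scr_mg_dl,
            "sofa": ep.sofa,
            "rrt": ep.rrt,
            "source": ep.source,
            "intra_abdominal": ep.source == "intra_abdominal",
            "drug": ep.drug,
            "mode": ep.mode.value,
            "dose_mg": ep.regimen_initial.dose_mg,
            "interval_h": ep.regimen_initial.interval_h,
            "infusion_h": ep.regimen_initial.infusion_h,
            "cl_true_l_h": ep.cl_true_l_h,
            "v_true_l": ep.v_true_l,
            "organism": ep.organism,
            "mic_mg_l": ep.mic.value_mg_l,
            "mic_provenance": ep.mic.provenance.value,
            "days_to_tdm": ep.days_to_tdm,
            "ke_per_h": ep.pk_estimate.ke_per_h if ep.pk_estimate else np.nan,
            "cl_hat_l_h": ep.pk_estimate.clearance_l_h if ep.pk_estimate else np.nan,
            "v_hat_l": ep.pk_estimate.volume_l if ep.pk_estimate else np.nan,
            "ft_above_mic_pct": ep.ft_above_mic_pct,
            "ft_above_4mic_pct": ep.ft_above_4mic_pct,
            "fcmin_over_mic": ep.fcmin_over_mic,
            "target_multiplier": ep.target_multiplier,
            "post_dose_mg": ep.regimen_post.dose_mg,
            "post_interval_h": ep.regimen_post.interval_h,
            "post_infusion_h": ep.regimen_post.infusion_h,
            "change_group": ep.change_group,
            "ordinal_code": ep.ordinal_code,
            "best_effort": ep.best_effort,
            "clinical_cure": ep.clinical_cure,
            "mortality_30d": ep.mortality_30d,
            "los_days": ep.los_days if ep.los_days is not None else np.nan,
            "censored": ep.censored,
        })
    return pd.DataFrame(rows)


def samples_frame(episodes: Sequence[InfectionEpisode]) -> pd.DataFrame:
    rows = []
    for ep in episodes:
        for s in ep.samples:
            rows.append({
                "episode_id": ep.episode_id,
                "drug": ep.drug,
                "dose_mg": ep.regimen_initial.dose_mg,
                "interval_h": ep.regimen_initial.interval_h,
                "infusion_h": ep.regimen_initial.infusion_h,
                "mode": ep.mode.value,
                "sample_kind": s.kind.value,
                "time_after_dose_start_h": s.time_after_dose_start_h,
                "total_conc_mg_L": s.total_conc_mg_l,
            })
    return pd.DataFrame(rows)


def isolates_frame(episodes: Sequence[InfectionEpisode]) -> pd.DataFrame:
    rows = []
    for ep in episodes:
        if ep.mic.provenance is MICProvenance.MEASURED_MAX:
            rows.append({
                "episode_id": ep.episode_id,
                "organism": ep.organism,
                "mic_mg_L": ep.mic.value_mg_l,
                "site": ep.source,
            })
    return pd.DataFrame(rows)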