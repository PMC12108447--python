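"""Steady-state one-compartment beta-lactam kinetics and PK/PD target attainment.

Individual kinetics are reconstructed from routine TDM samples: a peak drawn
shortly after the end of the infusion and a trough drawn before the next dose
(intermittent and extended infusions), or one to two random samples during a
continuous infusion.  The elimination rate constant comes from the log ratio of
the two elimination-phase concentrations; the steady-state profile is then the
closed-form superposition of a zero-order infusion and first-order elimination.

Free (unbound) concentrations are obtained by scaling total concentrations with
a fixed, drug-specific unbound fraction.  Target attainment is expressed as the
percentage of the dosing interval with free concentration above h x MIC
(fT>h*MIC, h = 1..5) and as the free trough to MIC ratio (fCmin/MIC).

Units are fixed throughout: hours, mg, L, mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "InfusionMode",
    "SampleKind",
    "DrugProfile",
    "Regimen",
    "ConcentrationSample",
    "PKEstimate",
    "TargetAttainment",
    "PKError",
    "UnknownDrugError",
    "DRUG_PROFILES",
    "estimate_elimination_rate",
    "reconstruct_profile",
    "free_concentration",
    "fraction_time_above",
    "target_attainment",
    "continuous_attainment",
    "predict_steady_state",
    "concentration_at",
]

DEFAULT_MULTIPLIERS = (1, 2, 3, 4, 5)


class PKError(ValueError):
    """Raised when concentration data cannot support a kinetic estimate."""


class UnknownDrugError(KeyError):
    """Raised when a drug has no configured unbound fraction."""


class InfusionMode(str, Enum):
    INTERMITTENT = "intermittent"
    EXTENDED = "extended"
    CONTINUOUS = "continuous"


class SampleKind(str, Enum):
    PEAK = "peak"
    TROUGH = "trough"
    RANDOM = "random"


@dataclass(frozen=True)
class DrugProfile:
    """A beta-lactam with its unbound fraction and allowed dosing menu.

    ``fraction_unbound`` is 1 minus the assumed protein-bound fraction.
    ``dose_menu`` lists the (dose mg, interval h, infusion h) combinations the
    regimen-recommendation search may return; it reflects label dosing and is
    configuration, not clinical advice.
    """

    drug_name: str
    fraction_unbound: float
    dose_menu: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction_unbound <= 1.0):
            raise ValueError(
                f"fraction_unbound must be in (0, 1], got {self.fraction_unbound}"
            )


def _menu(doses: Sequence[float], intervals: Sequence[float],
          infusions: Sequence[float]) -> tuple[tuple[float, float, float], ...]:
    return tuple(
        (d, tau, tinf)
        for d in doses for tau in intervals for tinf in infusions
        if tinf <= tau
    )


#: Default drug table.  Bound fractions: ampicillin 20%, aztreonam 56%,
#: cefazolin 80%, cefepime 20%, ceftriaxone 90%, meropenem 2%, oxacillin 95%,
#: piperacillin 30%.  Drugs quantified only "as needed" without a configured
#: binding fraction (amoxicillin, imipenem, nafcillin) are deliberately absent:
#: requesting them raises UnknownDrugError rather than silently defaulting.
DRUG_PROFILES: Mapping[str, DrugProfile] = {
    "ampicillin": DrugProfile("ampicillin", 0.80, _menu([1000, 2000, 3000], [4, 6, 8], [0.5, 2, 4])),
    "aztreonam": DrugProfile("aztreonam", 0.44, _menu([1000, 2000], [6, 8, 12], [0.5, 2, 4])),
    "cefazolin": DrugProfile("cefazolin", 0.20, _menu([1000, 2000, 3000], [6, 8], [0.5, 2])),
    "cefepime": DrugProfile("cefepime", 0.80, _menu([1000, 2000], [6, 8, 12, 24], [0.5, 3, 4])),
    "ceftriaxone": DrugProfile("ceftriaxone", 0.10, _menu([1000, 2000], [12, 24], [0.5])),
    "meropenem": DrugProfile("meropenem", 0.98, _menu([500, 1000, 2000], [6, 8, 12], [0.5, 3])),
    "oxacillin": DrugProfile("oxacillin", 0.05, _menu([1000, 2000], [4, 6], [0.5])),
    "piperacillin": DrugProfile("piperacillin", 0.70, _menu([3000, 4000], [4, 6, 8], [0.5, 4])),
}


def get_drug_profile(drug_name: str,
                     table: Mapping[str, DrugProfile] = DRUG_PROFILES) -> DrugProfile:
    try:
        return table[drug_name]
    except KeyError:
        raise UnknownDrugError(
            f"no unbound fraction configured for drug {drug_name!r}; "
            f"known drugs: {sorted(table)}"
        ) from None


@dataclass(frozen=True)
class Regimen:
    """A dosing prescription: dose (mg) every ``interval_h`` hours, infused
    over ``infusion_h`` hours.  Continuous infusions are represented on a 24 h
    reference window (interval_h = infusion_h = 24, dose = daily dose)."""

    drug_name: str
    dose_mg: float
    interval_h: float
    infusion_h: float
    mode: InfusionMode = InfusionMode.INTERMITTENT

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError(f"dose must be positive, got {self.dose_mg}")
        if not (0 < self.infusion_h <= self.interval_h):
            raise ValueError(
                f"infusion duration {self.infusion_h} h must lie in "
                f"(0, interval {self.interval_h} h]"
            )

    @property
    def daily_dose_mg(self) -> float:
        return self.dose_mg * 24.0 / self.interval_h

    @property
    def doses_per_day(self) -> float:
        return 24.0 / self.interval_h

    @staticmethod
    def classify_mode(infusion_h: float, interval_h: float,
                      intermittent_max_h: float = 1.0) -> InfusionMode:
        """Convention: intermittent when T_inf <= 1 h, extended when
        1 h < T_inf < tau, continuous when the infusion spans the interval."""
        if infusion_h >= interval_h:
            return InfusionMode.CONTINUOUS
        if infusion_h <= intermittent_max_h:
            return InfusionMode.INTERMITTENT
        return InfusionMode.EXTENDED


@dataclass(frozen=True)
class ConcentrationSample:
    """A timed total plasma concentration (mg/L), clocked from dose start."""

    time_after_dose_start_h: float
    total_conc_mg_l: float
    kind: SampleKind = SampleKind.RANDOM

    def __post_init__(self) -> None:
        if self.total_conc_mg_l <= 0:
            raise ValueError(
                f"total concentration must be positive, got {self.total_conc_mg_l}"
            )


@dataclass(frozen=True)
class PKEstimate:
    """Reconstructed steady-state kinetics for one TDM occasion."""

    ke_per_h: float
    half_life_h: float
    clearance_l_h: float
    volume_l: float
    cmax_ss_total: float
    cmin_ss_total: float


@dataclass(frozen=True)
class TargetAttainment:
    """fT>h*MIC (percent of interval, h in multipliers) plus fCmin/MIC."""

    ft_above: Mapping[int, float]
    fcmin_over_mic: float


def estimate_elimination_rate(
    s1: ConcentrationSample, s2: ConcentrationSample
) -> tuple[float, float]:
    """First-order elimination rate from two elimination-phase samples.

    ke = ln(C1/C2) / (t2 - t1);  t_half = ln 2 / ke.

    Raises :class:`PKError` when the samples are mis-ordered in time or when
    the concentrations are rising or flat (no elimination signal).
    """
    dt = s2.time_after_dose_start_h - s1.time_after_dose_start_h
    if dt <= 0:
        raise PKError(
            f"second sample must be later than the first "
            f"(t1={s1.time_after_dose_start_h} h, t2={s2.time_after_dose_start_h} h)"
        )
    c1, c2 = s1.total_conc_mg_l, s2.total_conc_mg_l
    if c1 <= c2:
        raise PKError(
            f"non-positive elimination signal: concentrations rising or flat "
            f"(C1={c1} mg/L at t1, C2={c2} mg/L at t2)"
        )
    ke = math.log(c1 / c2) / dt
    return ke, math.log(2.0) / ke


def reconstruct_profile(
    regimen: Regimen,
    peak: ConcentrationSample,
    trough: ConcentrationSample,
) -> PKEstimate:
    """Reconstruct steady-state one-compartment kinetics from a peak/trough pair.

    The measured peak (drawn after the end of the infusion) is extrapolated
    back to the end of infusion to give Cmax_ss; the measured trough is taken
    as Cmin_ss; clearance follows from the steady-state intermittent-infusion
    equation and V = CL / ke.
    """
    if peak.time_after_dose_start_h < regimen.infusion_h:
        raise PKError(
            f"peak drawn at {peak.time_after_dose_start_h} h, before the end of "
            f"the {regimen.infusion_h} h infusion: not on the elimination phase"
        )
    ke, t_half = estimate_elimination_rate(peak, trough)
    cmax = peak.total_conc_mg_l * math.exp(
        ke * (peak.time_after_dose_start_h - regimen.infusion_h)
    )
    cmin = trough.total_conc_mg_l
    tau, tinf = regimen.interval_h, regimen.infusion_h
    cl = (
        regimen.dose_mg
        * (1.0 - math.exp(-ke * tinf))
        / (tinf * cmax * (1.0 - math.exp(-ke * tau)))
    )
    if cl <= 0 or not math.isfinite(cl):
        raise PKError(f"non-physical clearance {cl} L/h reconstructed")
    return PKEstimate(
        ke_per_h=ke,
        half_life_h=t_half,
        clearance_l_h=cl,
        volume_l=cl / ke,
        cmax_ss_total=cmax,
        cmin_ss_total=cmin,
    )


def predict_steady_state(
    clearance_l_h: float, volume_l: float, regimen: Regimen
) -> PKEstimate:
    """Steady-state Cmax/Cmin for known (CL, V) under a regimen.

    Used both by the regimen-recommendation search (linear kinetics: the
    profile for any candidate follows from the reconstructed CL and V) and by
    the cohort simulator as the forward model.
    """
    if clearance_l_h <= 0 or volume_l <= 0:
        raise PKError("clearance and volume must be positive")
    ke = clearance_l_h / volume_l
    tau, tinf = regimen.interval_h, regimen.infusion_h
    if regimen.mode is InfusionMode.CONTINUOUS:
        css = regimen.dose_mg / tau / clearance_l_h  # plateau of the infusion
        return PKEstimate(ke, math.log(2.0) / ke, clearance_l_h, volume_l, css, css)
    cmax = (
        regimen.dose_mg
        * (1.0 - math.exp(-ke * tinf))
        / (tinf * clearance_l_h * (1.0 - math.exp(-ke * tau)))
    )
    cmin = cmax * math.exp(-ke * (tau - tinf))
    return PKEstimate(ke, math.log(2.0) / ke, clearance_l_h, volume_l, cmax, cmin)


def free_concentration(total_mg_l: float, drug: DrugProfile | str) -> float:
    """Free concentration = total x unbound fraction."""
    if total_mg_l < 0:
        raise ValueError(f"total concentration must be non-negative, got {total_mg_l}")
    profile = get_drug_profile(drug) if isinstance(drug, str) else drug
    return total_mg_l * profile.fraction_unbound


def concentration_at(pk: PKEstimate, regimen: Regimen, t: float) -> float:
    """Total concentration at time t (h from dose start) on the steady-state
    interval.  Infusion phase: C(t) = A(1 - e^{-ke t}) + Cmin e^{-ke t}, with A
    fixed by C(T_inf) = Cmax; elimination phase: C(t) = Cmax e^{-ke (t - T_inf)}."""
    ke = pk.ke_per_h
    tinf = regimen.infusion_h
    t = t % regimen.interval_h
    if regimen.mode is InfusionMode.CONTINUOUS:
        return pk.cmax_ss_total
    if t >= tinf:
        return pk.cmax_ss_total * math.exp(-ke * (t - tinf))
    ei = math.exp(-ke * tinf)
    a = (pk.cmax_ss_total - pk.cmin_ss_total * ei) / (1.0 - ei)
    e = math.exp(-ke * t)
    return a * (1.0 - e) + pk.cmin_ss_total * e


def fraction_time_above(
    pk: PKEstimate, regimen: Regimen, drug: DrugProfile | str, threshold_mg_l: float
) -> float:
    """Percent of the steady-state dosing interval with free concentration
    above ``threshold_mg_l``, from the closed-form profile.

    Crossing times are found with logarithms: the elimination phase decays
    exponentially from Cmax; the infusion phase rises monotonically from Cmin
    toward the infusion plateau.  Boundary convention: a free trough exactly at
    the threshold counts as attained (contact in the limit), while a free peak
    exactly at the threshold does not (measure-zero contact).
    """
    if threshold_mg_l <= 0:
        raise ValueError(f"threshold must be positive, got {threshold_mg_l}")
    profile = get_drug_profile(drug) if isinstance(drug, str) else drug
    fu = profile.fraction_unbound
    fcmax = pk.cmax_ss_total * fu
    fcmin = pk.cmin_ss_total * fu
    if regimen.mode is InfusionMode.CONTINUOUS:
        return 100.0 if fcmax > threshold_mg_l else 0.0
    if fcmin >= threshold_mg_l:
        return 100.0
    if fcmax <= threshold_mg_l:
        return 0.0
    ke = pk.ke_per_h
    tau, tinf = regimen.interval_h, regimen.infusion_h
    # Elimination phase: Cmax e^{-ke (t - tinf)} falls through the threshold.
    t_down = tinf + math.log(fcmax / threshold_mg_l) / ke
    t_down = min(t_down, tau)
    # Infusion phase: rises from fcmin (< threshold) toward the plateau.
    ei = math.exp(-ke * tinf)
    a = (fcmax - fcmin * ei) / (1.0 - ei)  # free-scale plateau
    # a > fcmax > threshold on this branch, so the crossing exists in (0, tinf).
    t_up = -math.log((a - threshold_mg_l) / (a - fcmin)) / ke
    return 100.0 * (t_down - t_up) / tau


def target_attainment(
    pk: PKEstimate,
    regimen: Regimen,
    drug: DrugProfile | str,
    mic_mg_l: float,
    multipliers: Iterable[int] = DEFAULT_MULTIPLIERS,
) -> TargetAttainment:
    """fT>h*MIC for each multiplier h, plus the fCmin/MIC ratio."""
    if mic_mg_l <= 0:
        raise ValueError(f"MIC must be positive, got {mic_mg_l}")
    profile = get_drug_profile(drug) if isinstance(drug, str) else drug
    ft = {
        int(h): fraction_time_above(pk, regimen, profile, h * mic_mg_l)
        for h in multipliers
    }
    fcmin = pk.cmin_ss_total * profile.fraction_unbound
    return TargetAttainment(ft_above=ft, fcmin_over_mic=fcmin / mic_mg_l)


def continuous_attainment(
    samples: Sequence[ConcentrationSample],
    drug: DrugProfile | str,
    mic_mg_l: float,
    multipliers: Iterable[int] = DEFAULT_MULTIPLIERS,
) -> TargetAttainment:
    """Attainment under a continuous infusion from random plateau samples.

    Css is the arithmetic mean of the sampled totals; the free plateau either
    clears a threshold for the whole interval or never does.
    """
    if not samples:
        raise PKError("at least one random sample is required for a continuous infusion")
    if mic_mg_l <= 0:
        raise ValueError(f"MIC must be positive, got {mic_mg_l}")
    profile = get_drug_profile(drug) if isinstance(drug, str) else drug
    css = sum(s.total_conc_mg_l for s in samples) / len(samples)
    fcss = css * profile.fraction_unbound
    ft = {int(h): (100.0 if fcss > h * mic_mg_l else 0.0) for h in multipliers}
    return TargetAttainment(ft_above=ft, fcmin_over_mic=fcss / mic_mg_l)
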