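"""Therapy-change classification and PK/PD-driven regimen recommendation.

A therapy increase is an increase in daily dose, frequency, and/or infusion
duration; a decrease is the converse.  Changes are coded ordinally (+1
increase, 0 no change, -1 decrease) for the outcome models.  Mixed-direction
edits (e.g. dose up, frequency down) are not defined by that rule and are
resolved by comparing predicted target attainment under the two regimens —
exposure is the axis the coding is meant to capture.

Regimen recommendation searches the drug's dose menu for the least intensive
candidate predicted (via the reconstructed CL and V; linear kinetics) to hold
the free concentration above the target multiple of the MIC for the whole
interval.  When no candidate attains the target, the maximal-attainment
candidate is returned flagged best-effort.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from functools import lru_cache
from typing import Sequence

from .mic import EffectiveMIC
from .pk import (
    DrugProfile,
    InfusionMode,
    PKEstimate,
    Regimen,
    fraction_time_above,
    predict_steady_state,
)

__all__ = [
    "ChangeDirection",
    "ChangeClassification",
    "RegimenRecommendation",
    "classify_change",
    "recommend_regimen",
    "predicted_attainment",
]

_REL_TOL = 1e-9


class ChangeDirection(IntEnum):
    DECREASE = -1
    NO_CHANGE = 0
    INCREASE = 1

    @property
    def label(self) -> str:
        return {-1: "decrease", 0: "no_change", 1: "increase"}[int(self)]


@dataclass(frozen=True)
class ChangeClassification:
    ordinal_code: ChangeDirection
    reasons: tuple[str, ...]

    @property
    def label(self) -> str:
        return self.ordinal_code.label


@dataclass(frozen=True)
class RegimenRecommendation:
    regimen: Regimen
    predicted_ft_above_target_pct: float
    best_effort: bool


def _cmp(a: float, b: float) -> int:
    if a > b * (1 + _REL_TOL) + _REL_TOL:
        return 1
    if a < b * (1 - _REL_TOL) - _REL_TOL:
        return -1
    return 0


def predicted_attainment(
    pk: PKEstimate,
    regimen: Regimen,
    drug: DrugProfile,
    mic_mg_l: float,
    target_multiplier: int = 1,
) -> float:
    """Predicted fT>target_multiplier*MIC (%) for a regimen, given the
    patient's reconstructed clearance and volume."""
    ss = predict_steady_state(pk.clearance_l_h, pk.volume_l, regimen)
    return fraction_time_above(ss, regimen, drug, target_multiplier * mic_mg_l)


def classify_change(
    old: Regimen,
    new: Regimen,
    pk: PKEstimate | None = None,
    drug: DrugProfile | None = None,
    mic_mg_l: float | None = None,
    target_multiplier: int = 1,
) -> ChangeClassification:
    """Code a regimen edit as increase (+1), no change (0) or decrease (-1).

    Components compared: daily dose (dose x 24 / tau), frequency (24 / tau)
    and infusion duration.  Any component strictly up with none down is an
    increase; the converse a decrease.  Mixed directions need the optional PK
    context (pk, drug, mic) and are resolved by predicted attainment.
    """
    if old.drug_name != new.drug_name:
        raise ValueError(
            f"cannot classify a drug switch ({old.drug_name} -> {new.drug_name})"
        )
    comparisons = {
        "daily-dose": _cmp(new.daily_dose_mg, old.daily_dose_mg),
        "frequency": _cmp(new.doses_per_day, old.doses_per_day),
        "infusion-duration": _cmp(new.infusion_h, old.infusion_h),
    }
    ups = tuple(k for k, v in comparisons.items() if v > 0)
    downs = tuple(k for k, v in comparisons.items() if v < 0)
    if not ups and not downs:
        return ChangeClassification(ChangeDirection.NO_CHANGE, ())
    if ups and not downs:
        return ChangeClassification(ChangeDirection.INCREASE, ups)
    if downs and not ups:
        return ChangeClassification(ChangeDirection.DECREASE, downs)
    # Mixed directions: fall back to predicted exposure at the episode MIC.
    if pk is None or drug is None or mic_mg_l is None:
        raise ValueError(
            "mixed-direction regimen change needs pk, drug and mic context "
            f"to resolve (up: {ups}, down: {downs})"
        )
    att_old = predicted_attainment(pk, old, drug, mic_mg_l, target_multiplier)
    att_new = predicted_attainment(pk, new, drug, mic_mg_l, target_multiplier)
    direction = _cmp(att_new, att_old)
    reason = (f"mixed-direction resolved by predicted attainment "
              f"({att_old:.1f}% -> {att_new:.1f}%)",)
    return ChangeClassification(ChangeDirection(direction), reason if direction else ())


@lru_cache(maxsize=64)
def _candidates(drug: DrugProfile, intermittent_max_h: float = 1.0) -> tuple[Regimen, ...]:
    return tuple(
        Regimen(drug.drug_name, dose, tau, tinf,
                Regimen.classify_mode(tinf, tau, intermittent_max_h))
        for dose, tau, tinf in drug.dose_menu
    )


def recommend_regimen(
    pk: PKEstimate,
    drug: DrugProfile,
    mic: EffectiveMIC | float,
    target_multiplier: int = 1,
    menu: Sequence[Regimen] | None = None,
    current: Regimen | None = None,
) -> RegimenRecommendation:
    """Least intensive menu regimen predicted to reach 100% fT>h*MIC.

    Candidates attaining 100% are ranked by total daily dose, then by number
    of daily administrations, then by infusion duration; the current regimen
    wins ties so an adequate prescription is never edited gratuitously.  With
    no attaining candidate the maximal-attainment one is returned with
    ``best_effort`` set.
    """
    mic_value = mic.value_mg_l if isinstance(mic, EffectiveMIC) else float(mic)
    if mic_value <= 0:
        raise ValueError(f"MIC must be positive, got {mic_value}")
    candidates = list(menu) if menu is not None else _candidates(drug)
    if current is not None and current not in candidates:
        candidates.append(current)
    if not candidates:
        raise ValueError(f"empty dose menu for {drug.drug_name}")

    def rank(r: Regimen) -> tuple:
        # current-regimen preference only breaks exact ties
        return (r.daily_dose_mg, r.doses_per_day, r.infusion_h, r != current)

    scored = [
        (r, predicted_attainment(pk, r, drug, mic_value, target_multiplier))
        for r in candidates
    ]
    attaining = [(r, a) for r, a in scored if a >= 100.0 - 1e-9]
    if attaining:
        best = min(attaining, key=lambda ra: rank(ra[0]))
        return RegimenRecommendation(best[0], best[1], best_effort=False)
    best = max(scored, key=lambda ra: (ra[1],) + tuple(-x for x in rank(ra[0])[:3]))
    return RegimenRecommendation(best[0], best[1], best_effort=True)
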