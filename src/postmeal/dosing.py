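"""Mealtime insulin bolus algorithms.

Three dosing rules for multiple-daily-injection therapy:

* **Carbohydrate counting (CC)** — the guideline standard: dose =
  carbohydrate grams divided by the insulin-to-carbohydrate ratio (ICR).
  Fat and protein are ignored.
* **Modified fat-protein-unit (FPU) algorithm** — one FPU is 200 kcal of
  fat or protein and is dosed like 10 g of carbohydrate, added on top of
  the carbohydrate dose through the same ICR.
* **Original Pankowska equation** — identical construction with a
  100 kcal FPU, i.e. twice the fat/protein insulin of the modified rule.

The ICR is estimated from the total daily dose (TDD) with the 500 rule,
ICR = 500 / TDD grams per unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .meals import MealComposition

#: kcal of fat/protein per FPU in the modified algorithm.
MODIFIED_KCAL_PER_FPU = 200.0
#: kcal of fat/protein per FPU in the original Pankowska equation.
PANKOWSKA_KCAL_PER_FPU = 100.0
#: one FPU is dosed like this many grams of carbohydrate.
CARB_G_PER_FPU = 10.0


class Algorithm(str, Enum):
    CC = "CC"
    FPU_MODIFIED = "FPU_MODIFIED"
    FPU_PANKOWSKA = "FPU_PANKOWSKA"


@dataclass(frozen=True)
class PatientParams:
    """Per-patient insulin parameters.

    ``icr_g_per_unit`` may be given directly or derived from ``tdd_units``
    with the 500 rule.  ``dose_increment_units`` is the pen delivery
    increment; 0 means no rounding.
    """

    tdd_units: float | None = None
    icr_g_per_unit: float | None = None
    dose_increment_units: float = 0.0

    def __post_init__(self) -> None:
        if self.icr_g_per_unit is None:
            if self.tdd_units is None:
                raise ValueError("provide icr_g_per_unit or tdd_units")
            object.__setattr__(self, "icr_g_per_unit", compute_icr(self.tdd_units))
        if not (self.icr_g_per_unit > 0 and math.isfinite(self.icr_g_per_unit)):
            raise ValueError(f"icr_g_per_unit must be positive, got {self.icr_g_per_unit!r}")
        if self.tdd_units is not None and self.tdd_units <= 0:
            raise ValueError("tdd_units must be positive")
        if self.dose_increment_units < 0:
            raise ValueError("dose_increment_units must be non-negative")


@dataclass(frozen=True)
class BolusResult:
    """Dose decomposition for one meal under one algorithm.

    ``total_units`` is the exact sum ``carb_units + fpu_units``;
    ``delivered_units`` is that total after rounding to the pen
    increment (equal to ``total_units`` when the increment is 0).
    """

    algorithm: Algorithm
    carb_equivalent_g: float
    fpu_raw: float
    fpu_counted: float
    carb_units: float
    fpu_units: float
    total_units: float
    delivered_units: float


def _round_half_up(x: float) -> float:
    # round-half-to-even would under-dose exactly-half FPU counts
    return math.floor(x + 0.5)


def compute_icr(tdd_units: float) -> float:
    """Insulin-to-carbohydrate ratio (g/U) from the 500 rule: 500 / TDD."""
    if not (tdd_units > 0 and math.isfinite(tdd_units)):
        raise ValueError(f"tdd_units must be positive and finite, got {tdd_units!r}")
    return 500.0 / tdd_units


def protein_fat_energy(meal: MealComposition) -> float:
    """Energy (kcal) from protein and fat: 4·protein_g + 9·fat_g."""
    return meal.protein_fat_kcal


def fpu_count(
    meal: MealComposition,
    kcal_per_fpu: float = MODIFIED_KCAL_PER_FPU,
    mode: str = "rounded",
) -> float:
    """Number of fat-protein units in a meal.

    ``mode='rounded'`` rounds half-up to a whole unit (clinical counting);
    ``mode='fractional'`` keeps the exact quotient.
    """
    if not (kcal_per_fpu > 0 and math.isfinite(kcal_per_fpu)):
        raise ValueError(f"kcal_per_fpu must be positive, got {kcal_per_fpu!r}")
    raw = protein_fat_energy(meal) / kcal_per_fpu
    if mode == "fractional":
        return raw
    if mode == "rounded":
        return float(_round_half_up(raw))
    raise ValueError(f"mode must be 'rounded' or 'fractional', got {mode!r}")


def round_dose(units: float, increment: float) -> float:
    """Round a dose to the nearest pen increment, half-up; 0 disables."""
    if increment < 0:
        raise ValueError(f"increment must be non-negative, got {increment!r}")
    if increment == 0:
        return units
    return _round_half_up(units / increment) * increment


def cc_bolus(meal: MealComposition, params: PatientParams) -> BolusResult:
    """Carbohydrate-counting bolus: carb_g / ICR, no fat/protein term."""
    carb_units = meal.carb_g / params.icr_g_per_unit
    return BolusResult(
        algorithm=Algorithm.CC,
        carb_equivalent_g=meal.carb_g,
        fpu_raw=0.0,
        fpu_counted=0.0,
        carb_units=carb_units,
        fpu_units=0.0,
        total_units=carb_units,
        delivered_units=round_dose(carb_units, params.dose_increment_units),
    )


def fpu_bolus(
    meal: MealComposition,
    params: PatientParams,
    kcal_per_fpu: float = MODIFIED_KCAL_PER_FPU,
    mode: str = "rounded",
) -> BolusResult:
    """Fat-protein-unit bolus: (carb_g + 10·FPU) / ICR.

    Each counted FPU adds 10 g of carbohydrate equivalent, dosed through
    the same ICR as the carbohydrate itself.  ``kcal_per_fpu=200`` gives
    the modified algorithm, ``100`` the original Pankowska equation.
    """
    counted = fpu_count(meal, kcal_per_fpu, mode)
    raw = protein_fat_energy(meal) / kcal_per_fpu
    carb_equivalent = meal.carb_g + CARB_G_PER_FPU * counted
    total = carb_equivalent / params.icr_g_per_unit
    carb_units = meal.carb_g / params.icr_g_per_unit
    algorithm = (
        Algorithm.FPU_PANKOWSKA
        if kcal_per_fpu == PANKOWSKA_KCAL_PER_FPU
        else Algorithm.FPU_MODIFIED
    )
    return BolusResult(
        algorithm=algorithm,
        carb_equivalent_g=carb_equivalent,
        fpu_raw=raw,
        fpu_counted=counted,
        carb_units=carb_units,
        fpu_units=total - carb_units,
        total_units=total,
        delivered_units=round_dose(total, params.dose_increment_units),
    )


def pankowska_bolus(
    meal: MealComposition, params: PatientParams, mode: str = "rounded"
) -> BolusResult:
    """Original Pankowska bolus (100 kcal per FPU)."""
    return fpu_bolus(meal, params, PANKOWSKA_KCAL_PER_FPU, mode)


def dose_ratio(
    meal: MealComposition,
    kcal_per_fpu: float = MODIFIED_KCAL_PER_FPU,
    mode: str = "rounded",
) -> float:
    """FPU-bolus / CC-bolus dose ratio; independent of the patient's ICR."""
    if meal.carb_g == 0:
        raise ValueError("dose ratio undefined for a carbohydrate-free meal")
    counted = fpu_count(meal, kcal_per_fpu, mode)
    return (meal.carb_g + CARB_G_PER_FPU * counted) / meal.carb_g
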