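"""Test-meal compositions.

A meal is described by its macronutrient masses in grams.  Energy is
derived with the Atwater factors (4 kcal/g carbohydrate and protein,
9 kcal/g fat); fiber carries no energy and attracts no insulin.

Two built-in breakfast fixtures ship with the package: ``NPM`` (normal
protein meal: milk, egg, 50 g beef, 75 g whole-wheat bread) and ``HPFM``
(high protein-fat meal: milk, egg, 150 g beef, 37.5 g bread).  They are
isocaloric but shift roughly one 200-kcal fat-protein block from
carbohydrate to protein/fat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

KCAL_PER_G_CARB = 4.0
KCAL_PER_G_PROTEIN = 4.0
KCAL_PER_G_FAT = 9.0


@dataclass(frozen=True)
class MealComposition:
    """Macronutrient content of one meal, masses in grams."""

    name: str
    carb_g: float
    protein_g: float
    fat_g: float
    fiber_g: float = 0.0

    def __post_init__(self) -> None:
        for field in ("carb_g", "protein_g", "fat_g", "fiber_g"):
            value = getattr(self, field)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{field} must be finite and non-negative, got {value!r}")

    @property
    def energy_kcal(self) -> float:
        """Total metabolizable energy of the meal."""
        return (
            KCAL_PER_G_CARB * self.carb_g
            + KCAL_PER_G_PROTEIN * self.protein_g
            + KCAL_PER_G_FAT * self.fat_g
        )

    @property
    def protein_fat_kcal(self) -> float:
        """Energy contributed by protein and fat only (drives FPU counting)."""
        return KCAL_PER_G_PROTEIN * self.protein_g + KCAL_PER_G_FAT * self.fat_g


#: Normal protein meal (53 g carbohydrate, 32 g protein, 17 g fat).
NPM = MealComposition("NPM", carb_g=53.0, protein_g=32.0, fat_g=17.0, fiber_g=0.05)

#: High protein-fat meal (35 g carbohydrate, 49 g protein, 18.5 g fat).
HPFM = MealComposition("HPFM", carb_g=35.0, protein_g=49.0, fat_g=18.5, fiber_g=0.04)

BUILTIN_MEALS = {"NPM": NPM, "HPFM": HPFM}
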