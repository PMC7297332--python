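"""Dosimeter-reading conversions.

Operational quantities: Hp(10) (personal dose equivalent at 10 mm depth,
whole-body relevant) and Hp(0.07) (0.07 mm depth, skin/lens relevant).
A collar-level Hp(10) reading is converted to Hp(0.07) by adding 3%.

Effective dose is estimated from collar/apron dosimeters with the modified
Niklason two-dosimeter algorithm

    E = 0.02 · (Hos − Hu) + Hu

where Hos is Hp(0.07) over the shield at thyroid level and Hu is Hp(10)
under the apron, or — assuming Hu ≈ 0.01·Hos when only the collar dosimeter
is worn — with the single-dosimeter form E = 0.03 · Hos.  The eye (lens)
dose is estimated from an unshielded neck dosimeter as 0.75 × the neck dose.

All conversions are linear and homogeneous; results carry their operational
quantity so the +3% depth conversion cannot be applied twice.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "QuantityDepth",
    "EffectiveDoseMethod",
    "DosimeterReading",
    "hp10_to_hp007",
    "effective_dose_two_dosimeter",
    "effective_dose_single_dosimeter",
    "eye_dose_from_neck",
    "effective_dose",
]

HP10_TO_HP007_FACTOR = 1.03
SHIELD_TRANSMISSION = 0.02  # weight of the over-shield term in the two-dosimeter formula
SINGLE_DOSIMETER_FACTOR = 0.03  # E = 0.03·Hos, assuming Hu ≈ 0.01·Hos
EYE_FROM_NECK_FACTOR = 0.75


class QuantityDepth(str, enum.Enum):
    HP10 = "HP10"
    HP007 = "HP007"


class EffectiveDoseMethod(str, enum.Enum):
    """How the whole-body dose fed to the risk engine is derived.

    ``HP10_RAW`` takes the collar Hp(10) reading as the whole-body dose
    (the study convention, and the default); the Niklason variants are
    alternative estimators.
    """

    HP10_RAW = "hp10_raw"
    NIKLASON_TWO = "niklason_two"
    NIKLASON_SINGLE = "niklason_single"


@dataclass
class DosimeterReading:
    """Collar (over-shield) and optional under-apron readings, in μSv.

    ``quantity_depth`` records the operational quantity of
    ``h_over_shield`` so depth conversion is applied at most once.
    """

    h_over_shield: float
    h_under_apron: float | None = None
    quantity_depth: QuantityDepth = QuantityDepth.HP10

    def __post_init__(self) -> None:
        self.quantity_depth = QuantityDepth(self.quantity_depth)
        if self.h_over_shield < 0:
            raise ValueError(f"negative over-shield reading {self.h_over_shield}")
        if self.h_under_apron is not None and self.h_under_apron < 0:
            raise ValueError(f"negative under-apron reading {self.h_under_apron}")

    def as_hp007(self) -> "DosimeterReading":
        """Return a reading whose over-shield value is expressed as Hp(0.07)."""
        if self.quantity_depth is QuantityDepth.HP007:
            return self
        return DosimeterReading(
            h_over_shield=hp10_to_hp007(self.h_over_shield),
            h_under_apron=self.h_under_apron,
            quantity_depth=QuantityDepth.HP007,
        )


def hp10_to_hp007(hp10: float) -> float:
    """Convert a collar-level Hp(10) reading to Hp(0.07) (+3%)."""
    if hp10 < 0:
        raise ValueError(f"negative Hp(10) reading {hp10}")
    return hp10 * HP10_TO_HP007_FACTOR


def effective_dose_two_dosimeter(hos: float, hu: float) -> float:
    """Modified Niklason two-dosimeter effective dose, E = 0.02·(Hos − Hu) + Hu.

    ``hos`` is Hp(0.07) over the shield at thyroid level, ``hu`` is Hp(10)
    under the apron; both in μSv.
    """
    if hos < 0 or hu < 0:
        raise ValueError("dosimeter readings must be non-negative")
    return SHIELD_TRANSMISSION * (hos - hu) + hu


def effective_dose_single_dosimeter(hos: float) -> float:
    """Single-collar-dosimeter effective dose, E = 0.03·Hos (Hu ≈ 0.01·Hos)."""
    if hos < 0:
        raise ValueError("dosimeter reading must be non-negative")
    return SINGLE_DOSIMETER_FACTOR * hos


def eye_dose_from_neck(neck_dose: float) -> float:
    """Eye (lens) dose from an unshielded neck dosimeter: 0.75 × neck dose."""
    if neck_dose < 0:
        raise ValueError("neck dose must be non-negative")
    return EYE_FROM_NECK_FACTOR * neck_dose


def effective_dose(
    reading: DosimeterReading,
    method: EffectiveDoseMethod = EffectiveDoseMethod.HP10_RAW,
) -> float:
    """Whole-body dose (μSv) from a dosimeter reading under a chosen estimator."""
    method = EffectiveDoseMethod(method)
    if method is EffectiveDoseMethod.HP10_RAW:
        if reading.quantity_depth is not QuantityDepth.HP10:
            raise ValueError("hp10_raw requires an Hp(10) over-shield reading")
        return reading.h_over_shield
    converted = reading.as_hp007()
    if method is EffectiveDoseMethod.NIKLASON_SINGLE:
        return effective_dose_single_dosimeter(converted.h_over_shield)
    if converted.h_under_apron is None:
        raise ValueError("niklason_two requires an under-apron reading")
    return effective_dose_two_dosimeter(
        converted.h_over_shield, converted.h_under_apron
    )
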