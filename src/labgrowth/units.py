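"""Unit handling rules of the questionnaire database, reproduced bit-exactly.

Owners entered measurements in their preferred units; the database converted
and stored them with fixed rounded constants (2.54 cm/inch, 2.20 lb/kg,
28.3 g/oz).  Those rounded constants — not higher-precision physical
constants — are used verbatim here, because fidelity to the stored values is
what matters for reanalysis.

The same module defines the three latent unit-error classes for heights and
the multipliers that undo each error.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Conversion constants exactly as applied by the questionnaire database.
CM_PER_INCH = 2.54
LB_PER_KG = 2.20
G_PER_OZ = 28.3

#: Latent unit-error classes for stored heights, in canonical order.
#: ``cm2in``: measured in cm, entered in the inches field -> stored 2.54x too
#: large.  ``ok``: correct.  ``in2cm``: measured in inches, entered in the cm
#: field -> stored 2.54x too small.
CLASS_LABELS = ("cm2in", "ok", "in2cm")

#: Multiplicative distortion each class applies to the stored value.
CLASS_MEAN_MULTIPLIERS = (CM_PER_INCH, 1.0, 1.0 / CM_PER_INCH)

_HEIGHT_UNITS = {"cm", "inch"}
_WEIGHT_UNITS = {"kg", "lb"}
_FOOD_UNITS = {"g", "oz"}


class UnitError(ValueError):
    """Raised when a measurement carries a unit of the wrong dimension."""


@dataclass(frozen=True)
class Measurement:
    """A raw owner entry: a nonnegative value plus its declared unit."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"measurement value must be nonnegative, got {self.value}")
        if self.unit not in _HEIGHT_UNITS | _WEIGHT_UNITS | _FOOD_UNITS:
            raise UnitError(f"unknown unit {self.unit!r}")


def store_height_cm(m: Measurement) -> float:
    """Database storage rule for heights: inches are multiplied by 2.54."""
    if m.unit not in _HEIGHT_UNITS:
        raise UnitError(f"height must be in cm or inch, got {m.unit!r}")
    return m.value * CM_PER_INCH if m.unit == "inch" else m.value


def store_weight_kg(m: Measurement) -> float:
    """Database storage rule for dog weights: pounds are divided by 2.20."""
    if m.unit not in _WEIGHT_UNITS:
        raise UnitError(f"weight must be in kg or lb, got {m.unit!r}")
    return m.value / LB_PER_KG if m.unit == "lb" else m.value


def store_food_g(m: Measurement) -> float:
    """Database storage rule for food masses: ounces are multiplied by 28.3."""
    if m.unit not in _FOOD_UNITS:
        raise UnitError(f"food mass must be in g or oz, got {m.unit!r}")
    return m.value * G_PER_OZ if m.unit == "oz" else m.value


def correction_multiplier(class_label: str) -> float:
    """Multiplier that corrects a stored height given its error class.

    A ``cm2in`` record is stored 2.54x too large, so the correction is
    1/2.54; an ``in2cm`` record is stored 2.54x too small, so the correction
    is 2.54; ``ok`` records are left alone.  By construction
    ``correction_multiplier(c) * CLASS_MEAN_MULTIPLIERS[c] == 1`` for every
    class.
    """
    try:
        idx = CLASS_LABELS.index(class_label)
    except ValueError:
        raise UnitError(f"unknown error class {class_label!r}") from None
    return 1.0 / CLASS_MEAN_MULTIPLIERS[idx]
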