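"""Unit-safe concentrations and the Glucose Ketone Index.

The Glucose Ketone Index (GKI) is the molar ratio of circulating glucose to
β-hydroxybutyrate (β-OHB), the major circulating ketone body:

    GKI = [glucose (mM)] / [β-OHB (mM)]

Consumer glucose meters commonly report mg/dL while ketone meters report mM,
so every concentration here carries an explicit analyte and unit, and the
ratio is always computed on millimolar values.  The mg/dL → mM divisor for an
analyte is its molar mass divided by ten (mg/dL × 10 = mg/L; mg/L ÷ g/mol =
mmol/L): 18.016 for glucose (180.16 g/mol) and 10.41 for β-OHB (104.1 g/mol).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "Analyte",
    "Unit",
    "Concentration",
    "GkiValue",
    "ValidationError",
    "DomainError",
    "convert",
    "compute_gki",
    "display_gki",
]


class ValidationError(ValueError):
    """Raised for structurally invalid inputs (negative values, wrong analyte)."""


class DomainError(ValueError):
    """Raised when a quantity is mathematically or physiologically undefined."""


class Analyte(enum.Enum):
    """Blood analyte with its fixed molar mass in g/mol.

    The molar masses are physical constants of the two molecules, not
    configuration: glucose C6H12O6 is 180.16 g/mol and β-hydroxybutyrate
    C4H8O3 is 104.1 g/mol.
    """

    GLUCOSE = ("glucose", 180.16)
    BETA_HYDROXYBUTYRATE = ("beta_hydroxybutyrate", 104.1)

    def __init__(self, label: str, molar_mass: float):
        self.label = label
        self.molar_mass = molar_mass

    @property
    def mg_dl_per_mm(self) -> float:
        """mg/dL corresponding to 1 mM: molar mass / 10."""
        return self.molar_mass / 10.0

    @classmethod
    def from_label(cls, label: str) -> "Analyte":
        label = label.strip().lower().replace("-", "_").replace(" ", "_")
        aliases = {
            "glucose": cls.GLUCOSE,
            "beta_hydroxybutyrate": cls.BETA_HYDROXYBUTYRATE,
            "bhb": cls.BETA_HYDROXYBUTYRATE,
            "b_ohb": cls.BETA_HYDROXYBUTYRATE,
            "bohb": cls.BETA_HYDROXYBUTYRATE,
            "ketone": cls.BETA_HYDROXYBUTYRATE,
            "ketones": cls.BETA_HYDROXYBUTYRATE,
        }
        try:
            return aliases[label]
        except KeyError:
            raise ValidationError(f"unknown analyte: {label!r}") from None


class Unit(enum.Enum):
    MG_PER_DL = "mg/dL"
    MM = "mM"

    @classmethod
    def from_label(cls, label: str) -> "Unit":
        norm = label.strip().lower().replace("_", "/").replace("per", "/").replace("//", "/")
        norm = norm.replace(" ", "")
        aliases = {
            "mg/dl": cls.MG_PER_DL,
            "mgdl": cls.MG_PER_DL,
            "mm": cls.MM,
            "mmol/l": cls.MM,
            "mmoll": cls.MM,
        }
        try:
            return aliases[norm]
        except KeyError:
            raise ValidationError(f"unknown unit: {label!r}") from None


@dataclass(frozen=True)
class Concentration:
    """An analyte amount with a mandatory explicit unit.

    Units are never guessed from magnitude — 5.5 is a plausible glucose value
    in both mM and (hypoglycemic) mg/dL, so ambiguity is a hard error at the
    type level.
    """

    analyte: Analyte
    value: float
    unit: Unit

    def __post_init__(self) -> None:
        if not isinstance(self.analyte, Analyte):
            raise ValidationError(f"analyte must be an Analyte, got {self.analyte!r}")
        if not isinstance(self.unit, Unit):
            raise ValidationError(f"unit must be a Unit, got {self.unit!r}")
        v = float(self.value)
        if not math.isfinite(v):
            raise ValidationError(f"concentration must be finite, got {self.value!r}")
        if v < 0:
            raise ValidationError(f"concentration must be non-negative, got {self.value!r}")
        object.__setattr__(self, "value", v)

    @property
    def mM(self) -> float:
        """The value expressed in mM regardless of stored unit."""
        if self.unit is Unit.MM:
            return self.value
        return self.value / self.analyte.mg_dl_per_mm

    def to(self, target_unit: Unit) -> "Concentration":
        return convert(self, target_unit)


def convert(c: Concentration, target_unit: Unit) -> Concentration:
    """Convert a concentration between mg/dL and mM.

    mM = (mg/dL) / (molar_mass / 10) and mg/dL = mM × (molar_mass / 10);
    the analyte is preserved and converting to the same unit returns an
    equal concentration.
    """
    if not isinstance(target_unit, Unit):
        raise ValidationError(f"unknown target unit: {target_unit!r}")
    if c.unit is target_unit:
        return Concentration(c.analyte, c.value, c.unit)
    factor = c.analyte.mg_dl_per_mm
    if target_unit is Unit.MM:
        return Concentration(c.analyte, c.value / factor, Unit.MM)
    return Concentration(c.analyte, c.value * factor, Unit.MG_PER_DL)


@dataclass(frozen=True)
class GkiValue:
    """A dimensionless glucose/ketone molar ratio.

    ``display`` renders the conventional one-decimal presentation, rounding
    half away from zero so e.g. 15.1666… prints as "15.2" and 1.0 keeps its
    trailing zero ("1.0").
    """

    value: float

    def __post_init__(self) -> None:
        v = float(self.value)
        if not math.isfinite(v) or v < 0:
            raise ValidationError(f"GKI must be finite and non-negative, got {self.value!r}")
        object.__setattr__(self, "value", v)

    @property
    def display(self) -> str:
        return display_gki(self)

    def __float__(self) -> float:
        return self.value


def compute_gki(
    glucose: Concentration,
    ketone: Concentration,
    *,
    allow_zero_glucose: bool = False,
) -> GkiValue:
    """Compute the Glucose Ketone Index from paired concentrations.

    Inputs are converted to mM internally, so the result is independent of
    the units the meters reported.  Zero ketones make the ratio undefined
    (meters have a minimum quantifiable value, so a true zero is a data
    problem, not infinity).  Zero glucose is physiologically implausible and
    rejected unless ``allow_zero_glucose`` is set, in which case the GKI is 0.
    """
    if glucose.analyte is not Analyte.GLUCOSE:
        raise ValidationError(f"glucose argument has analyte {glucose.analyte.label}")
    if ketone.analyte is not Analyte.BETA_HYDROXYBUTYRATE:
        raise ValidationError(f"ketone argument has analyte {ketone.analyte.label}")
    ketone_mm = ketone.mM
    if ketone_mm == 0:
        raise DomainError("GKI undefined for zero ketones")
    glucose_mm = glucose.mM
    if glucose_mm == 0 and not allow_zero_glucose:
        raise DomainError("zero glucose is physiologically implausible; pass allow_zero_glucose=True to force")
    return GkiValue(glucose_mm / ketone_mm)


def display_gki(g: GkiValue | float) -> str:
    """One-decimal string for a GKI, rounding half away from zero.

    Uses decimal arithmetic on the shortest repr of the float so binary
    representation noise (e.g. 2.675 stored as 2.67499…) cannot flip the
    rounding direction.
    """
    v = float(g)
    if not math.isfinite(v):
        raise ValidationError(f"cannot display non-finite GKI {v!r}")
    return str(Decimal(repr(v)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
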