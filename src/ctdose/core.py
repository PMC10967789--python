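"""Per-patient CT dose arithmetic.

The scanner-reported dose indices (CTDIvol, DLP) are referenced to a
standard 32-cm PMMA cylinder, not to the patient.  This module implements
the size-adjustment chain used to convert them into patient-specific
quantities:

* effective diameter  ``Deff = sqrt(AP × LAT)``  — the diameter of the
  circle whose area matches the (elliptical) chest cross-section at its
  most extensive slice;
* size-specific dose estimate  ``SSDE = CTDIvol × k(Deff)``;
* size-specific dose-length product  ``DLPss = DLP × k(Deff)``, the
  whole-scan analogue of SSDE;
* effective dose  ``ED = DLP × f``  with a protocol-specific coefficient
  (chest: 0.014 mSv/(mGy·cm));
* scan-length change of the diagnostic acquisition relative to the
  planning topogram, for over-scanning audits.

All functions here are pure; conversion-factor lookup lives in
:mod:`ctdose.conversion` and cohort-level statistics in
:mod:`ctdose.cohort`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "DomainError",
    "Sex",
    "ScanChangeCategory",
    "PatientRecord",
    "DerivedDose",
    "ScanLengthChange",
    "CHEST_F_FACTOR",
    "effective_diameter",
    "ssde",
    "dlp_ss",
    "effective_dose",
    "scan_length_change",
]

#: Adult chest effective-dose coefficient, mSv per mGy·cm (AAPM Report 96).
CHEST_F_FACTOR = 0.014

#: Tolerance for the BMI-consistency flag on records, kg/m².
BMI_CONSISTENCY_TOL = 0.5


class DomainError(ValueError):
    """A physical quantity is outside its valid domain."""

    def __init__(self, field_name: str, value: float, requirement: str):
        self.field_name = field_name
        self.value = value
        super().__init__(f"{field_name}={value!r} violates: {requirement}")


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class ScanChangeCategory(str, enum.Enum):
    SHORTENED = "shortened"
    UNCHANGED = "unchanged"
    EXTENDED = "extended"


def _require_positive(name: str, value: float) -> None:
    if not value > 0 or not math.isfinite(value):
        raise DomainError(name, value, "must be finite and > 0")


def _require_nonnegative(name: str, value: float) -> None:
    if value < 0 or not math.isfinite(value):
        raise DomainError(name, value, "must be finite and >= 0")


@dataclass(frozen=True)
class PatientRecord:
    """One chest-CT study row from a dose report.

    Lengths are carried in mm, cross-sectional dimensions in cm,
    dose-length products in mGy·cm.  ``ctdi_vol`` is referenced to the
    32-cm body phantom.  ``ap <= lat`` is typical for the chest but is
    deliberately not enforced; real records may violate it.
    """

    id: str
    sex: Sex
    age: float            # years
    height: float         # cm
    weight: float         # kg
    bmi: float            # kg/m²
    ap: float             # cm, anterior–posterior at most extensive slice
    lat: float            # cm, lateral at the same slice
    topogram_length: float     # mm
    diagnostic_length: float   # mm
    ctdi_vol: float            # mGy
    dlp_topogram: float        # mGy·cm
    dlp_diagnostic: float      # mGy·cm

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        for name in ("age", "height", "weight", "bmi", "ap", "lat",
                     "topogram_length", "diagnostic_length"):
            _require_positive(name, getattr(self, name))
        for name in ("ctdi_vol", "dlp_topogram", "dlp_diagnostic"):
            _require_nonnegative(name, getattr(self, name))

    @property
    def bmi_consistent(self) -> bool:
        """True when bmi agrees with weight/(height/100)² within 0.5 kg/m².

        Inconsistency is a flag, not a rejection: dose reports sometimes
        carry a stale BMI.
        """
        return abs(self.bmi - self.weight / (self.height / 100.0) ** 2) <= BMI_CONSISTENCY_TOL


@dataclass(frozen=True)
class DerivedDose:
    """Computed size-adjustment chain for one record."""

    d_eff: float   # cm
    k: float       # dimensionless conversion factor
    ssde: float    # mGy
    dlp_ss: float  # mGy·cm
    ed: float      # mSv


@dataclass(frozen=True)
class ScanLengthChange:
    """Diagnostic-scan length relative to the planning topogram."""

    delta_mm: float
    delta_pct: float
    category: ScanChangeCategory = field(init=False)

    def __post_init__(self) -> None:
        if self.delta_mm < 0:
            cat = ScanChangeCategory.SHORTENED
        elif self.delta_mm > 0:
            cat = ScanChangeCategory.EXTENDED
        else:
            cat = ScanChangeCategory.UNCHANGED
        object.__setattr__(self, "category", cat)


def effective_diameter(ap: float, lat: float) -> float:
    """Geometric-mean effective diameter sqrt(AP × LAT), in cm.

    Symmetric in its arguments and homogeneous of degree one.
    """
    _require_positive("ap", ap)
    _require_positive("lat", lat)
    return math.sqrt(ap * lat)


def ssde(ctdi_vol: float, k: float) -> float:
    """Size-specific dose estimate CTDIvol × k, in mGy."""
    _require_nonnegative("ctdi_vol", ctdi_vol)
    _require_positive("k", k)
    return ctdi_vol * k


def dlp_ss(dlp: float, k: float) -> float:
    """Size-specific dose-length product DLP × k, in mGy·cm.

    By construction ``dlp_ss(dlp, k)/dlp == ssde(c, k)/c == k`` for any
    record, so the whole-scan adjustment is exactly the per-slice one.
    """
    _require_nonnegative("dlp", dlp)
    _require_positive("k", k)
    return dlp * k


def effective_dose(dlp: float, f_factor: float = CHEST_F_FACTOR) -> float:
    """Effective dose DLP × f, in mSv.

    Exactly linear in DLP: summing phase-wise DLPs then converting equals
    converting then summing.
    """
    _require_nonnegative("dlp", dlp)
    _require_positive("f_factor", f_factor)
    return dlp * f_factor


def scan_length_change(topogram_mm: float, diagnostic_mm: float) -> ScanLengthChange:
    """Length change of the diagnostic scan against the topogram.

    ``delta_mm = diagnostic − topogram``; ``delta_pct`` is that change as a
    percentage of the topogram length.  The category is the sign of
    ``delta_mm``, with "unchanged" requiring exact mm equality.
    """
    _require_positive("topogram_mm", topogram_mm)
    _require_positive("diagnostic_mm", diagnostic_mm)
    delta = diagnostic_mm - topogram_mm
    return ScanLengthChange(delta_mm=delta, delta_pct=100.0 * delta / topogram_mm)
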