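"""Size-to-conversion-factor tables.

The SSDE conversion factor k maps a phantom-referenced CTDIvol to a
patient-size-specific dose.  For the 32-cm body phantom the factor is a
decreasing function of effective diameter (larger patients attenuate
more, so the phantom over-states their dose less); the packaged table is
transcribed from AAPM Report No. 204 together with that report's
exponential fit, which is retained as a cross-check.

Effective-dose coefficients f (ED = DLP × f) per protocol come from AAPM
Report No. 96 and are shipped as a small YAML map; chest is 0.014
mSv/(mGy·cm).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ConfigurationError",
    "UnknownProtocolError",
    "Phantom",
    "ExponentialFit",
    "ConversionTable",
    "FFactorTable",
    "body_32cm_table",
    "default_f_factors",
    "lookup_k",
    "lookup_f",
]

logger = logging.getLogger("ctdose")


class ConfigurationError(ValueError):
    """A table or configuration object is unusable."""


class UnknownProtocolError(KeyError):
    def __init__(self, protocol: str, known: tuple[str, ...]):
        self.protocol = protocol
        self.known = known
        super().__init__(
            f"unknown protocol {protocol!r}; known protocols: {', '.join(known)}"
        )

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


class Phantom(str, enum.Enum):
    BODY_32CM = "body_32cm"
    HEAD_16CM = "head_16cm"


@dataclass(frozen=True)
class ExponentialFit:
    """k = a·exp(−b·d) model published alongside the tabulated factors."""

    a: float
    b: float

    def __call__(self, d_eff: float | np.ndarray) -> float | np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(d_eff, dtype=float))


@dataclass(frozen=True)
class ConversionTable:
    """Monotone map from effective diameter (cm) to conversion factor k."""

    phantom: Phantom
    diameters: np.ndarray   # cm, strictly increasing
    factors: np.ndarray     # dimensionless, strictly decreasing
    fit: ExponentialFit | None = None
    source: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        k = np.asarray(self.factors, dtype=float)
        if d.size == 0 or k.size == 0:
            raise ConfigurationError("conversion table is empty")
        if d.size != k.size:
            raise ConfigurationError("diameters and factors differ in length")
        if not np.all(np.diff(d) > 0):
            raise ConfigurationError("effective diameters must be strictly increasing")
        if not np.all(np.diff(k) < 0):
            raise ConfigurationError("conversion factors must be strictly decreasing")
        object.__setattr__(self, "diameters", d)
        object.__setattr__(self, "factors", k)

    def lookup(self, d_eff: float, *, use_fit: bool = False) -> float:
        """k at ``d_eff`` by linear interpolation between tabulated knots.

        At a tabulated diameter the table entry is returned exactly.
        Outside the tabulated range the value is clamped to the nearest
        endpoint and a warning is logged — extrapolating the trend would
        eventually produce k < 1 nonsense at very large diameters.  With
        ``use_fit`` the exponential model is evaluated instead (same
        clamping policy).
        """
        if not d_eff > 0:
            raise ConfigurationError(f"d_eff={d_eff!r} must be > 0")
        lo, hi = self.diameters[0], self.diameters[-1]
        if d_eff < lo or d_eff > hi:
            clamped = min(max(d_eff, lo), hi)
            logger.warning(
                "effective diameter %.2f cm outside tabulated range "
                "[%.1f, %.1f] for %s; clamping to %.1f cm",
                d_eff, lo, hi, self.phantom.value, clamped,
            )
            d_eff = clamped
        if use_fit:
            if self.fit is None:
                raise ConfigurationError("table has no exponential fit")
            return float(self.fit(d_eff))
        return float(np.interp(d_eff, self.diameters, self.factors))

    def fit_table_max_relative_deviation(self) -> float:
        """Largest |fit − table|/table over the knots (cross-validation)."""
        if self.fit is None:
            raise ConfigurationError("table has no exponential fit")
        pred = self.fit(self.diameters)
        return float(np.max(np.abs(pred - self.factors) / self.factors))


#: Published exponential-fit coefficients for the 32-cm body phantom,
#: effective-diameter parameterisation (AAPM Report 204).
BODY_32CM_FIT = ExponentialFit(a=3.704369, b=0.03671937)

_BODY_TABLE_RESOURCE = "aapm204_body32_effective_diameter.tsv"
_F_FACTOR_RESOURCE = "f_factors.yaml"


def body_32cm_table() -> ConversionTable:
    """The packaged 32-cm body-phantom table (effective diameter 8–45 cm)."""
    ref = resources.files("ctdose.data").joinpath(_BODY_TABLE_RESOURCE)
    with ref.open("rb") as fh:
        d, k = _load_two_column(fh)
    return ConversionTable(
        phantom=Phantom.BODY_32CM,
        diameters=d,
        factors=k,
        fit=BODY_32CM_FIT,
        source="AAPM Report 204, 32-cm body phantom, effective diameter",
    )


def _load_two_column(fh) -> tuple[np.ndarray, np.ndarray]:
    rows = []
    for raw in fh.read().decode().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("d_eff"):
            continue
        a, b = line.split("\t")
        rows.append((float(a), float(b)))
    arr = np.asarray(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class FFactorTable:
    """Protocol name → effective-dose coefficient f, mSv/(mGy·cm)."""

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.factors:
            raise ConfigurationError("f-factor table is empty")
        for name, f in self.factors.items():
            if not f > 0:
                raise ConfigurationError(f"f-factor for {name!r} must be > 0, got {f}")
        object.__setattr__(self, "factors", dict(self.factors))

    def lookup(self, protocol: str) -> float:
        key = protocol.strip().lower()
        try:
            return self.factors[key]
        except KeyError:
            raise UnknownProtocolError(protocol, tuple(sorted(self.factors))) from None

    @property
    def protocols(self) -> tuple[str, ...]:
        return tuple(sorted(self.factors))


def default_f_factors() -> FFactorTable:
    ref = resources.files("ctdose.data").joinpath(_F_FACTOR_RESOURCE)
    with ref.open("r", encoding="utf-8") as fh:
        return FFactorTable(yaml.safe_load(fh))


def lookup_k(table: ConversionTable, d_eff: float, *, use_fit: bool = False) -> float:
    """Functional alias for :meth:`ConversionTable.lookup`."""
    return table.lookup(d_eff, use_fit=use_fit)


def lookup_f(table: FFactorTable, protocol: str) -> float:
    """Functional alias for :meth:`FFactorTable.lookup`."""
    return table.lookup(protocol)
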