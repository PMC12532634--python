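"""Unit conversions and (incremental) trapezoidal areas.

Every downstream index is a composition of three primitives defined here:
conversion between the clinical and SI unit systems for glucose, insulin and
HbA1c, and total / incremental areas under timed concentration curves computed
with the trapezoidal rule on the sampled grid (no interpolation).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimedSeries",
    "UnitSystem",
    "convert_glucose",
    "convert_insulin",
    "convert_hba1c",
    "trapezoid_auc",
    "incremental_auc",
    "round_half_up",
    "fraction_pct",
]

#: molar mass of anhydrous D-glucose, g/mol
GLUCOSE_MOLAR_MASS = 180.156

#: conventional insulin conversion, pmol/l per µU/ml
INSULIN_PMOL_PER_UU = 6.0

# NGSP/IFCC master equation coefficients: NGSP(%) = a * IFCC(mmol/mol) + b
_HBA1C_SLOPE = 0.09148
_HBA1C_INTERCEPT = 2.152


@dataclass(frozen=True)
class UnitSystem:
    """Conversion factors shared by all index calculations.

    The insulin factor is the common clinical convention of 6.0 pmol/l per
    µU/ml; set ``insulin_pmol_per_uU=6.945`` for the WHO alternative.
    """

    glucose_molar_mass: float = GLUCOSE_MOLAR_MASS
    insulin_pmol_per_uU: float = INSULIN_PMOL_PER_UU

    def __post_init__(self) -> None:
        if self.glucose_molar_mass <= 0 or self.insulin_pmol_per_uU <= 0:
            raise ValueError("unit-system factors must be positive")


@dataclass(frozen=True)
class TimedSeries:
    """Analyte concentrations sampled at minutes since the glucose load.

    ``times`` must be strictly increasing with the first sample the fasting
    one (t = 0 by convention); ``values`` are non-negative concentrations in
    the units named by ``unit`` (e.g. ``"mmol/l"``, ``"pmol/l"``).
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D and equally long")
        if t.size == 0:
            raise ValueError("empty series")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("values must be finite and non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def value_at(self, t: float) -> float:
        """Value at a sampled time; raises if ``t`` was not sampled."""
        idx = np.nonzero(np.isclose(self.times, t))[0]
        if idx.size == 0:
            raise ValueError(f"time {t} min not sampled (grid: {self.times.tolist()})")
        return float(self.values[idx[0]])

    def has_times(self, required) -> bool:
        return all(np.any(np.isclose(self.times, t)) for t in required)


def convert_glucose(
    value: float, from_unit: str, to_unit: str, units: UnitSystem | None = None
) -> float:
    """Convert a glucose concentration between mg/dl and mmol/l.

    mg/dl -> mmol/l divides by (molar mass / 10); e.g. 100 mg/dl is
    5.55 mmol/l, which rounds to the clinical threshold pair 100 / 5.6.
    """
    units = units or UnitSystem()
    if value < 0:
        raise ValueError("glucose concentration must be non-negative")
    factor = units.glucose_molar_mass / 10.0  # mg/dl per mmol/l
    known = {"mg/dl", "mmol/l"}
    if from_unit not in known or to_unit not in known:
        raise ValueError(f"unknown glucose unit; expected one of {sorted(known)}")
    if from_unit == to_unit:
        return value
    if from_unit == "mg/dl":
        return value / factor
    return value * factor


def convert_insulin(
    value: float, from_unit: str, to_unit: str, units: UnitSystem | None = None
) -> float:
    """Convert insulin (or C-peptide) between µU/ml and pmol/l."""
    units = units or UnitSystem()
    if value < 0:
        raise ValueError("insulin concentration must be non-negative")
    known = {"uU/ml", "pmol/l"}
    if from_unit not in known or to_unit not in known:
        raise ValueError(f"unknown insulin unit; expected one of {sorted(known)}")
    if from_unit == to_unit:
        return value
    if from_unit == "uU/ml":
        return value * units.insulin_pmol_per_uU
    return value / units.insulin_pmol_per_uU


def convert_hba1c(value: float, from_unit: str, to_unit: str) -> float:
    """Convert HbA1c between IFCC mmol/mol and NGSP percent.

    Uses the NGSP/IFCC master equation NGSP(%) = 0.09148 * IFCC + 2.152 and
    its inverse (39 mmol/mol <-> 5.7 %). Inputs outside the physiological
    range (10-200 mmol/mol, 3-20 %) are rejected.
    """
    known = {"mmol/mol", "%"}
    if from_unit not in known or to_unit not in known:
        raise ValueError(f"unknown HbA1c unit; expected one of {sorted(known)}")
    if from_unit == "mmol/mol" and not (10.0 <= value <= 200.0):
        raise ValueError("HbA1c outside 10-200 mmol/mol")
    if from_unit == "%" and not (3.0 <= value <= 20.0):
        raise ValueError("HbA1c outside 3-20 %")
    if from_unit == to_unit:
        return value
    if from_unit == "mmol/mol":
        return _HBA1C_SLOPE * value + _HBA1C_INTERCEPT
    return (value - _HBA1C_INTERCEPT) / _HBA1C_SLOPE


def _window(series: TimedSeries, t_start: float, t_end: float):
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    t = series.times
    i0 = np.nonzero(np.isclose(t, t_start))[0]
    i1 = np.nonzero(np.isclose(t, t_end))[0]
    if i0.size == 0 or i1.size == 0:
        raise ValueError(
            f"window [{t_start}, {t_end}] endpoints must be sampled times "
            f"(grid: {t.tolist()}); no interpolation is performed"
        )
    return int(i0[0]), int(i1[0])


def trapezoid_auc(series: TimedSeries, t_start: float, t_end: float) -> float:
    """Trapezoidal area under the curve over a sampled window, in value*min."""
    i0, i1 = _window(series, t_start, t_end)
    return float(np.trapezoid(series.values[i0 : i1 + 1], series.times[i0 : i1 + 1]))


def incremental_auc(series: TimedSeries, t_start: float, t_end: float) -> float:
    """Area above the value at ``t_start``; negative if the curve dips below it."""
    i0, i1 = _window(series, t_start, t_end)
    base = series.values[i0]
    seg = series.values[i0 : i1 + 1] - base
    return float(np.trapezoid(seg, series.times[i0 : i1 + 1]))


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, used when pairing printed clinical thresholds."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def fraction_pct(part: float, whole: float, ndigits: int = 1) -> float:
    """Percentage ``part/whole`` rounded half-up, for cohort breakdown tables."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round_half_up(100.0 * part / whole, ndigits)
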