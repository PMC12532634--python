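"""OGTT-derived insulin sensitivity, secretion, beta-cell-function and
clearance indices.

All indices operate on a single :class:`OGTTRecord` (one subject-visit of a
75 g oral glucose tolerance test sampled at 0/30/60/90/120 min) carrying
glucose in mmol/l and insulin / C-peptide in pmol/l; conversions to the
mg/dl / µU/ml system some formulas are defined in happen internally through
:class:`~prediarem.units.UnitSystem`.

The panel:

* OGIS — model-derived oral glucose insulin sensitivity (ml/min/m^2),
  120-min closed-form variant with the published regression constants.
* Matsuda composite whole-body insulin sensitivity index.
* Hepatic insulin-resistance index: glucose AUC x insulin AUC over 0-30 min.
* Muscle insulin-sensitivity index: post-peak glucose decay rate divided by
  mean insulin.
* Adipose insulin-resistance index: fasting NEFA x fasting insulin.
* Early-phase secretion index: C-peptide AUC(0-30) / glucose AUC(0-30).
* Adaptation index: secretion index x OGIS (secretion adjusted for
  sensitivity; the disposition-index analogue used here).
* Hepatic insulin clearance marker: C-peptide AUC(0-120) / insulin AUC(0-120).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import TimedSeries, UnitSystem, convert_glucose, convert_insulin, trapezoid_auc

__all__ = [
    "OGTTRecord",
    "IndexPanel",
    "OGISConstants",
    "bsa_dubois",
    "matsuda_isi",
    "ogis_120",
    "hepatic_ir",
    "muscle_isi",
    "adipose_ir",
    "secretion_index",
    "adaptation_index",
    "insulin_clearance",
    "compute_panel",
    "hyperbola_summary",
]

STANDARD_GRID = (0.0, 30.0, 60.0, 90.0, 120.0)


@dataclass
class OGTTRecord:
    """One visit's timed OGTT series plus fasting labs.

    Glucose in mmol/l; insulin and C-peptide in pmol/l; optional incretin /
    glucagon series in pmol/l; fasting NEFA in µmol/l; HbA1c in mmol/mol.
    """

    subject_id: str
    visit: str
    glucose: TimedSeries
    insulin: TimedSeries
    c_peptide: TimedSeries | None = None
    glp1: TimedSeries | None = None
    gip: TimedSeries | None = None
    glucagon: TimedSeries | None = None
    fasting_nefa: float | None = None
    hba1c: float | None = None
    glucose_dose: float = 75.0

    def __post_init__(self) -> None:
        if self.glucose_dose <= 0:
            raise ValueError("glucose dose must be positive")
        if not np.isclose(self.glucose.times[0], 0.0) or not np.isclose(
            self.insulin.times[0], 0.0
        ):
            raise ValueError("fasting (t=0) sample required for glucose and insulin")


@dataclass
class OGISConstants:
    """Regression constants of the published 120-min OGIS expression.

    The defaults are the 2-h protocol values (glucose in mg/dl, insulin in
    µU/ml, dose in g/m^2): p = (289, 270, 14000, 440, 637e-6, 117),
    glucose distribution volume 10^4 ml/m^2 and reference clamp glucose
    90 mg/dl.
    """

    p1: float = 289.0
    p2: float = 270.0
    p3: float = 14.0e3
    p4: float = 440.0
    p5: float = 637.0e-6
    p6: float = 117.0
    v_glucose: float = 1.0e4
    g_clamp_ref: float = 90.0


def bsa_dubois(weight_kg: float, height_m: float) -> float:
    """Body surface area (m^2) by the DuBois & DuBois formula."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight_kg**0.425 * (height_m * 100.0) ** 0.725


def _glucose_mgdl(record: OGTTRecord, units: UnitSystem) -> np.ndarray:
    return np.array(
        [convert_glucose(v, "mmol/l", "mg/dl", units) for v in record.glucose.values]
    )


def _insulin_uU(record: OGTTRecord, units: UnitSystem) -> np.ndarray:
    return np.array(
        [convert_insulin(v, "pmol/l", "uU/ml", units) for v in record.insulin.values]
    )


def matsuda_isi(record: OGTTRecord, units: UnitSystem | None = None) -> float:
    """Matsuda composite index: 10000 / sqrt(G0 * I0 * Gmean * Imean).

    Glucose in mg/dl, insulin in µU/ml; means taken over all sampled points.
    """
    units = units or UnitSystem()
    if not record.glucose.has_times(STANDARD_GRID) or not record.insulin.has_times(
        STANDARD_GRID
    ):
        raise ValueError("Matsuda index requires glucose and insulin at all 5 points")
    g = _glucose_mgdl(record, units)
    i = _insulin_uU(record, units)
    if np.any(g <= 0) or np.any(i <= 0):
        raise ValueError("Matsuda index requires strictly positive concentrations")
    prod = g[0] * i[0] * g.mean() * i.mean()
    return 10000.0 / math.sqrt(prod)


def ogis_120(
    record: OGTTRecord,
    body_surface_area: float,
    constants: OGISConstants | None = None,
    units: UnitSystem | None = None,
) -> float:
    """120-min OGIS (ml/min/m^2) from the published closed-form expression.

    Requires glucose at 0, 90 and 120 min and insulin at 0 and 90 min.  The
    expression is::

        cl  = p4 * ((p1*D - V*(G120 - G90)/30) / G90 + p3/G0) / (I90 - I0 + p2)
        ogis = (cl + sqrt(cl^2 + 4*p5*p6*(G90 - Gcl)*cl)) / 2

    with D the glucose dose per body surface area (g/m^2), V the glucose
    distribution volume and Gcl the reference clamp glucose.
    """
    constants = constants or OGISConstants()
    units = units or UnitSystem()
    if body_surface_area <= 0:
        raise ValueError("body surface area must be positive")
    needed_g, needed_i = (0.0, 90.0, 120.0), (0.0, 90.0)
    if not record.glucose.has_times(needed_g) or not record.insulin.has_times(needed_i):
        raise ValueError("OGIS-120 requires glucose at 0/90/120 and insulin at 0/90 min")
    g0 = convert_glucose(record.glucose.value_at(0.0), "mmol/l", "mg/dl", units)
    g90 = convert_glucose(record.glucose.value_at(90.0), "mmol/l", "mg/dl", units)
    g120 = convert_glucose(record.glucose.value_at(120.0), "mmol/l", "mg/dl", units)
    i0 = convert_insulin(record.insulin.value_at(0.0), "pmol/l", "uU/ml", units)
    i90 = convert_insulin(record.insulin.value_at(90.0), "pmol/l", "uU/ml", units)
    c = constants
    dose = record.glucose_dose / body_surface_area  # g per m^2
    cl = (
        c.p4
        * ((c.p1 * dose - c.v_glucose * (g120 - g90) / 30.0) / g90 + c.p3 / g0)
        / (i90 - i0 + c.p2)
    )
    disc = cl * cl + 4.0 * c.p5 * c.p6 * (g90 - c.g_clamp_ref) * cl
    return 0.5 * (cl + math.sqrt(disc))


def hepatic_ir(record: OGTTRecord, units: UnitSystem | None = None) -> float:
    """Hepatic insulin-resistance index: AUC_glucose(0-30) x AUC_insulin(0-30).

    Glucose AUC in mg/dl*min, insulin AUC in µU/ml*min.
    """
    units = units or UnitSystem()
    g = TimedSeries(record.glucose.times, _glucose_mgdl(record, units), "mg/dl")
    i = TimedSeries(record.insulin.times, _insulin_uU(record, units), "uU/ml")
    return trapezoid_auc(g, 0.0, 30.0) * trapezoid_auc(i, 0.0, 30.0)


def muscle_isi(record: OGTTRecord, units: UnitSystem | None = None) -> float:
    """Muscle insulin-sensitivity index.

    Rate of glucose decay (mg/dl/min, positive) from the OGTT glucose peak to
    the subsequent nadir, by least-squares slope over that span, divided by
    the mean insulin concentration (µU/ml).  Returns NaN (missing) when
    glucose never declines after its peak.
    """
    units = units or UnitSystem()
    g = _glucose_mgdl(record, units)
    i = _insulin_uU(record, units)
    t = record.glucose.times
    peak = int(np.argmax(g))
    if peak == len(g) - 1:
        return float("nan")  # monotonically rising: no decline phase
    nadir = peak + 1 + int(np.argmin(g[peak + 1 :]))
    tt, gg = t[peak : nadir + 1], g[peak : nadir + 1]
    slope = np.polyfit(tt, gg, 1)[0]  # mg/dl per min, <= 0 on the decline
    decay = max(-float(slope), 0.0)
    return decay / float(i.mean())


def adipose_ir(
    fasting_nefa_umol_l: float | None,
    fasting_insulin_pmol_l: float,
    units: UnitSystem | None = None,
) -> float:
    """Adipose insulin-resistance index: fasting NEFA (mmol/l) x insulin (µU/ml).

    NEFA is measured in a subgroup only; a missing value propagates as NaN.
    """
    units = units or UnitSystem()
    if fasting_nefa_umol_l is None or (
        isinstance(fasting_nefa_umol_l, float) and math.isnan(fasting_nefa_umol_l)
    ):
        return float("nan")
    if fasting_nefa_umol_l < 0 or fasting_insulin_pmol_l < 0:
        raise ValueError("NEFA and insulin must be non-negative")
    nefa_mmol = fasting_nefa_umol_l / 1000.0
    ins_uU = convert_insulin(fasting_insulin_pmol_l, "pmol/l", "uU/ml", units)
    return nefa_mmol * ins_uU


def secretion_index(record: OGTTRecord) -> float:
    """Early-phase insulin secretion: C-peptide AUC(0-30) / glucose AUC(0-30).

    C-peptide in pmol/l, glucose in mmol/l, so the ratio is in pmol/mmol.
    """
    if record.c_peptide is None:
        raise ValueError("C-peptide series required")
    auc_c = trapezoid_auc(record.c_peptide, 0.0, 30.0)
    auc_g = trapezoid_auc(record.glucose, 0.0, 30.0)
    if auc_g <= 0:
        raise ValueError("glucose AUC over 0-30 min must be positive")
    return auc_c / auc_g


def adaptation_index(secretion: float, ogis: float) -> float:
    """Beta-cell adaptation index: secretion index x OGIS (exact product)."""
    return secretion * ogis


def insulin_clearance(record: OGTTRecord) -> float:
    """Hepatic insulin clearance marker: C-peptide AUC(0-120) / insulin AUC(0-120)."""
    if record.c_peptide is None:
        raise ValueError("C-peptide series required")
    auc_c = trapezoid_auc(record.c_peptide, 0.0, 120.0)
    auc_i = trapezoid_auc(record.insulin, 0.0, 120.0)
    if auc_i <= 0:
        raise ValueError("insulin AUC over 0-120 min must be positive")
    return auc_c / auc_i


@dataclass
class IndexPanel:
    """Per-visit vector of sensitivity / secretion / clearance indices."""

    subject_id: str
    visit: str
    ogis: float
    matsuda: float
    hepatic_ir: float
    muscle_isi: float
    adipose_ir: float
    secretion_index: float
    adaptation_index: float
    insulin_clearance: float

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "visit": self.visit,
            "ogis": self.ogis,
            "matsuda": self.matsuda,
            "hepatic_ir": self.hepatic_ir,
            "muscle_isi": self.muscle_isi,
            "adipose_ir": self.adipose_ir,
            "secretion_index": self.secretion_index,
            "adaptation_index": self.adaptation_index,
            "insulin_clearance": self.insulin_clearance,
        }


def compute_panel(
    record: OGTTRecord,
    body_surface_area: float,
    constants: OGISConstants | None = None,
    units: UnitSystem | None = None,
) -> IndexPanel:
    """Compute the full index panel for one subject-visit."""
    units = units or UnitSystem()
    ogis = ogis_120(record, body_surface_area, constants, units)
    secr = secretion_index(record) if record.c_peptide is not None else float("nan")
    clear = insulin_clearance(record) if record.c_peptide is not None else float("nan")
    return IndexPanel(
        subject_id=record.subject_id,
        visit=record.visit,
        ogis=ogis,
        matsuda=matsuda_isi(record, units),
        hepatic_ir=hepatic_ir(record, units),
        muscle_isi=muscle_isi(record, units),
        adipose_ir=adipose_ir(record.fasting_nefa, record.insulin.value_at(0.0), units),
        secretion_index=secr,
        adaptation_index=adaptation_index(secr, ogis),
        insulin_clearance=clear,
    )


def hyperbola_summary(panels: pd.DataFrame) -> pd.DataFrame:
    """Group x visit medians (with s.e.m.) of OGIS and the secretion index.

    ``panels`` needs columns ``group``, ``visit``, ``ogis``,
    ``secretion_index``; the output is suitable for plotting baseline ->
    month-12 arrows on the sensitivity-secretion hyperbola.
    """
    required = {"group", "visit", "ogis", "secretion_index"}
    if not required.issubset(panels.columns):
        raise ValueError(f"panels must have columns {sorted(required)}")
    if panels.empty:
        raise ValueError("empty panel collection")
    out = (
        panels.groupby(["group", "visit"])
        .agg(
            ogis_median=("ogis", "median"),
            ogis_sem=("ogis", lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0),
            secretion_median=("secretion_index", "median"),
            secretion_sem=(
                "secretion_index",
                lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0,
            ),
            n=("ogis", "size"),
        )
        .reset_index()
    )
    return out
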