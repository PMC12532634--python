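"""Glycemic status, responder labelling and the non-weight-loss filter.

Status follows the ADA partition into normal glucose regulation (NGR),
prediabetes and type 2 diabetes (T2D).  NGR requires *all* of fasting
glucose < 5.6 mmol/l, post-load glucose below its criterion (2-h < 7.8
mmol/l, or 1-h < 8.6 mmol/l [155 mg/dl] in the one-hour variant) and
HbA1c < 39 mmol/mol; T2D requires *any* of fasting glucose >= 7.0 mmol/l,
2-h glucose >= 11.1 mmol/l or HbA1c >= 48 mmol/mol; everything in between
is prediabetes.  A responder (R) is a subject who has returned to NGR at
month 12; labels are only defined within the non-weight-loss stratum
(weight change >= 0 kg over the intervention).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GlycemicStatus",
    "GlycemicInputs",
    "ResponseLabel",
    "classify_status",
    "label_response",
    "non_weight_loss_filter",
    "transition_table",
    "NGR_FPG_MMOL",
    "NGR_2H_MMOL",
    "NGR_1H_MMOL",
    "NGR_HBA1C_MMOL_MOL",
    "T2D_FPG_MMOL",
    "T2D_2H_MMOL",
    "T2D_HBA1C_MMOL_MOL",
]

# NGR side (strict <) of the partition
NGR_FPG_MMOL = 5.6
NGR_2H_MMOL = 7.8
NGR_1H_MMOL = 8.6  # 155 mg/dl
NGR_HBA1C_MMOL_MOL = 39.0
# diabetes side (>=), ADA diagnostic thresholds
T2D_FPG_MMOL = 7.0
T2D_2H_MMOL = 11.1
T2D_HBA1C_MMOL_MOL = 48.0


class GlycemicStatus(str, enum.Enum):
    NGR = "NGR"
    PREDIABETES = "prediabetes"
    T2D = "T2D"


@dataclass(frozen=True)
class GlycemicInputs:
    """Glycemic measurements for one visit, all in mmol/l resp. mmol/mol."""

    fpg: float
    hba1c: float
    g120: float | None = None
    g60: float | None = None

    def __post_init__(self) -> None:
        for name in ("fpg", "hba1c", "g120", "g60"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v <= 0):
                raise ValueError(f"{name} must be positive when present")


@dataclass(frozen=True)
class ResponseLabel:
    label: str  # "R" or "NR"
    weight_change: float  # kg over the intervention


def classify_status(
    inputs: GlycemicInputs, criterion: str = "standard"
) -> GlycemicStatus:
    """Classify a visit into NGR / prediabetes / T2D.

    ``criterion='standard'`` applies the 2-h post-load cutoff;
    ``criterion='one_hour'`` replaces it with the 1-h 8.6 mmol/l (155 mg/dl)
    cutoff for separating NGR from prediabetes (the T2D side always uses the
    diagnostic 2-h threshold when a 2-h value is available).
    """
    if criterion not in ("standard", "one_hour"):
        raise ValueError("criterion must be 'standard' or 'one_hour'")
    if criterion == "standard" and inputs.g120 is None:
        raise ValueError("2-h glucose required for the standard criterion")
    if criterion == "one_hour" and inputs.g60 is None:
        raise ValueError("1-h glucose required for the one_hour criterion")

    if (
        inputs.fpg >= T2D_FPG_MMOL
        or (inputs.g120 is not None and inputs.g120 >= T2D_2H_MMOL)
        or inputs.hba1c >= T2D_HBA1C_MMOL_MOL
    ):
        return GlycemicStatus.T2D

    if criterion == "standard":
        postload_ok = inputs.g120 < NGR_2H_MMOL
    else:
        postload_ok = inputs.g60 < NGR_1H_MMOL
    if (
        inputs.fpg < NGR_FPG_MMOL
        and postload_ok
        and inputs.hba1c < NGR_HBA1C_MMOL_MOL
    ):
        return GlycemicStatus.NGR
    return GlycemicStatus.PREDIABETES


def label_response(
    status_month12: GlycemicStatus | None, weight_change: float = 0.0
) -> ResponseLabel | None:
    """R iff the month-12 status is NGR; None when the visit is missing."""
    if status_month12 is None:
        return None
    label = "R" if status_month12 == GlycemicStatus.NGR else "NR"
    return ResponseLabel(label=label, weight_change=weight_change)


def non_weight_loss_filter(weight0_kg: float, weight12_kg: float) -> bool:
    """True iff the subject did not lose weight (weight12 - weight0 >= 0)."""
    if weight0_kg <= 0 or weight12_kg <= 0 or not (
        math.isfinite(weight0_kg) and math.isfinite(weight12_kg)
    ):
        raise ValueError("weights must be positive and finite")
    return weight12_kg - weight0_kg >= 0.0


def transition_table(
    statuses_t1, statuses_t2, order=("NGR", "prediabetes", "T2D")
) -> pd.DataFrame:
    """3x3 count table of paired glycemic-status transitions.

    Rows index the first time point, columns the second; row sums equal the
    per-status cohort sizes at the first time point.
    """
    s1 = [GlycemicStatus(s).value for s in statuses_t1]
    s2 = [GlycemicStatus(s).value for s in statuses_t2]
    if len(s1) != len(s2):
        raise ValueError("status vectors must be paired (equal length)")
    cat1 = pd.Categorical(s1, categories=list(order))
    cat2 = pd.Categorical(s2, categories=list(order))
    return pd.crosstab(cat1, cat2, rownames=["from"], colnames=["to"], dropna=False)
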