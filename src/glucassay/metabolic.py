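"""Metabolic indices from per-animal plasma panels.

HOMA-IR (homeostasis model assessment of insulin resistance), the LDL/HDL
atherogenic ratio, percent reduction of an analyte against a reference
group, and per-group mean +/- SD summaries.

Units are part of the contract: fasting blood glucose in mmol/L and fasting
insulin in mIU/L, so HOMA-IR = FBG * INS / 22.5 (Matthews formulation).
Mixing mg/dL glucose silently corrupts the index, hence strict bounds checks.
"""

from __future__ import annotations

import enum
import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "Group",
    "MetabolicPanel",
    "ANALYTES",
    "homa_ir",
    "ldl_hdl_ratio",
    "pct_reduction_vs_reference",
    "group_summary",
]

HOMA_IR_DENOMINATOR = 22.5

ANALYTES = ("fbg", "insulin", "tc", "tg", "ldl", "hdl", "gsp")


class Group(str, enum.Enum):
    CONTROL = "CONTROL"  # non-diabetic, saline
    MODEL = "MODEL"  # diabetic, saline
    PPS_L = "PPS_L"  # diabetic, low-dose polysaccharide
    PPS_H = "PPS_H"  # diabetic, high-dose polysaccharide


class PanelError(ValueError):
    pass


class MetabolicPanel(BaseModel):
    """One subject's plasma panel.

    fbg mmol/L; insulin mIU/L; tc/tg/ldl/hdl mmol/L; gsp in assay units.
    Analytes may be absent (None); index functions raise when an input
    they need is missing.
    """

    model_config = ConfigDict(frozen=True)

    subject_id: str
    group: Group
    week: int = 0
    fbg: Optional[float] = None
    insulin: Optional[float] = None
    tc: Optional[float] = None
    tg: Optional[float] = None
    ldl: Optional[float] = None
    hdl: Optional[float] = None
    gsp: Optional[float] = None

    @model_validator(mode="after")
    def _validate(self):
        for name in ANALYTES:
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and non-negative")
        return self


def homa_ir(p: MetabolicPanel) -> float:
    """HOMA-IR = FBG (mmol/L) * insulin (mIU/L) / 22.5."""
    if p.fbg is None or p.insulin is None:
        raise PanelError("homa_ir needs both fbg and insulin")
    return p.fbg * p.insulin / HOMA_IR_DENOMINATOR


def ldl_hdl_ratio(p: MetabolicPanel) -> float:
    """Atherogenic LDL/HDL cholesterol ratio."""
    if p.ldl is None or p.hdl is None:
        raise PanelError("ldl_hdl_ratio needs both ldl and hdl")
    if p.hdl <= 0:
        raise PanelError("hdl must be positive")
    return p.ldl / p.hdl


def pct_reduction_vs_reference(value_treated: float, value_reference: float) -> float:
    """100 * (reference - treated) / reference.

    The reference is conventionally the disease-model group mean at the
    matched timepoint, so a positive value means the treatment lowered the
    analyte relative to untreated disease.
    """
    if value_reference <= 0:
        raise PanelError("reference value must be positive")
    return 100.0 * (value_reference - value_treated) / value_reference


def group_summary(panels: Iterable[MetabolicPanel]) -> pd.DataFrame:
    """Per-group mean and sample SD (ddof=1) of every present analyte.

    Returns a DataFrame indexed by group with columns ``<analyte>_mean``,
    ``<analyte>_sd`` and ``n``; SD is NaN for single-subject groups.
    """
    panels = list(panels)
    if not panels:
        raise PanelError("group_summary needs at least one panel")
    rows = [
        {"group": p.group.value, **{a: getattr(p, a) for a in ANALYTES}}
        for p in panels
    ]
    df = pd.DataFrame(rows)
    out = []
    for group, sub in df.groupby("group", sort=True):
        rec: dict[str, float | str | int] = {"group": group, "n": len(sub)}
        for a in ANALYTES:
            col = sub[a].dropna()
            rec[f"{a}_mean"] = col.mean() if len(col) else np.nan
            rec[f"{a}_sd"] = col.std(ddof=1) if len(col) > 1 else np.nan
        out.append(rec)
    return pd.DataFrame(out).set_index("group")
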