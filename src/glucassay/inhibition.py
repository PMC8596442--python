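"""Percent-inhibition statistics for plate-reader assays.

Covers the glucose-uptake inhibition assay on Caco-2 monolayers, the
radical-scavenging assays (DPPH, ABTS+, superoxide anion, hydroxyl) and the
alpha-glucosidase / alpha-amylase enzyme-inhibition assays.  All are
control-relative absorbance statistics:

    uptake / enzyme inhibition (%) = 100 * (AC - AS) / (AC - AB)
    scavenging (%)                 = 100 * (AC - (AS - AS0)) / AC

with AS, AC, AB the sample, control and blank absorbances and AS0 an
optional sample-without-reagent background well.  Negative values are
meaningful (promotion of uptake) and are never floored.
"""

from __future__ import annotations

import enum
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.stats import spearmanr

__all__ = [
    "Assay",
    "InhibitionMeasurement",
    "DoseResponseSeries",
    "DoseResponseSummary",
    "uptake_inhibition_rate",
    "scavenging_rate",
    "enzyme_inhibition_rate",
    "inhibition_rate",
    "summarize_dose_response",
    "mean_with_propagated_sd",
]


class Assay(str, enum.Enum):
    UPTAKE = "UPTAKE"
    DPPH = "DPPH"
    OH = "OH"
    SUPEROXIDE = "SUPEROXIDE"
    ABTS = "ABTS"
    GLUCOSIDASE = "GLUCOSIDASE"
    AMYLASE = "AMYLASE"


SCAVENGING_ASSAYS = {Assay.DPPH, Assay.OH, Assay.SUPEROXIDE, Assay.ABTS}
ENZYME_ASSAYS = {Assay.GLUCOSIDASE, Assay.AMYLASE}


class AssayError(ValueError):
    """Degenerate assay window or invalid measurement."""


class InhibitionMeasurement(BaseModel):
    """Absorbance triplet (sample, control, blank) for one assay condition."""

    model_config = ConfigDict(frozen=True)

    assay: Assay
    abs_sample_as: float
    abs_control_ac: float
    abs_blank_ab: float = 0.0
    abs_sample_background: Optional[float] = None

    @model_validator(mode="after")
    def _validate(self):
        for v in (self.abs_sample_as, self.abs_control_ac, self.abs_blank_ab):
            if v < 0:
                raise ValueError("absorbances must be non-negative")
        if self.abs_sample_background is not None and self.abs_sample_background < 0:
            raise ValueError("background absorbance must be non-negative")
        return self


class DoseResponseSeries(BaseModel):
    """Percent inhibition measured over a strictly increasing dose ladder (mg/mL)."""

    model_config = ConfigDict(frozen=True)

    assay: Assay
    concentrations: tuple[float, ...]
    inhibition_pct: tuple[float, ...]

    @model_validator(mode="after")
    def _validate(self):
        c = np.asarray(self.concentrations, dtype=float)
        if c.size != len(self.inhibition_pct):
            raise ValueError("concentrations and inhibition_pct must have equal length")
        if c.size and (np.any(c <= 0) or np.any(np.diff(c) <= 0)):
            raise ValueError("concentrations must be positive and strictly increasing")
        return self


class DoseResponseSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    assay: Assay
    max_inhibition_pct: float
    conc_at_max: float
    monotonicity_sign: int
    ic50_interp: Optional[float] = None


def uptake_inhibition_rate(m: InhibitionMeasurement) -> float:
    """Glucose-uptake inhibition: 100*(AC - AS)/(AC - AB).

    0% when the sample matches the control, 100% when it matches the blank;
    negative values indicate promotion of glucose uptake.
    """
    window = m.abs_control_ac - m.abs_blank_ab
    if window == 0:
        raise AssayError("degenerate assay window: AC = AB")
    return 100.0 * (m.abs_control_ac - m.abs_sample_as) / window


def scavenging_rate(m: InhibitionMeasurement, background_corrected: bool = True) -> float:
    """Radical-scavenging rate: 100*(AC - (AS - AS0))/AC.

    AS0 is the sample-without-reagent background (defaults to 0 when absent
    or when ``background_corrected`` is False).  Returns the raw value;
    report layers may clip to [-100, 100] for display.
    """
    if m.abs_control_ac <= 0:
        raise AssayError("control absorbance must be positive")
    background = (
        m.abs_sample_background
        if (background_corrected and m.abs_sample_background is not None)
        else 0.0
    )
    return 100.0 * (m.abs_control_ac - (m.abs_sample_as - background)) / m.abs_control_ac


def enzyme_inhibition_rate(m: InhibitionMeasurement) -> float:
    """Enzyme inhibition: 100*(1 - (AS - AB)/(AC - AB)).

    Algebraically identical to ``uptake_inhibition_rate``; kept as its own
    entry point so enzyme plates can carry their own blank convention.
    """
    window = m.abs_control_ac - m.abs_blank_ab
    if window == 0:
        raise AssayError("degenerate assay window: AC = AB")
    return 100.0 * (1.0 - (m.abs_sample_as - m.abs_blank_ab) / window)


def inhibition_rate(m: InhibitionMeasurement, background_corrected: bool = True) -> float:
    """Dispatch to the formula appropriate for the measurement's assay."""
    if m.assay in SCAVENGING_ASSAYS:
        return scavenging_rate(m, background_corrected=background_corrected)
    if m.assay in ENZYME_ASSAYS:
        return enzyme_inhibition_rate(m)
    return uptake_inhibition_rate(m)


def summarize_dose_response(s: DoseResponseSeries) -> DoseResponseSummary:
    """Max inhibition, its dose, the Spearman monotonicity sign, and the
    linearly interpolated dose at 50% inhibition when the series crosses it."""
    if len(s.concentrations) < 2:
        raise AssayError("dose-response summary needs at least 2 concentrations")
    conc = np.asarray(s.concentrations, dtype=float)
    pct = np.asarray(s.inhibition_pct, dtype=float)
    imax = int(np.argmax(pct))
    if np.all(pct == pct[0]):
        sign = 0
    else:
        rho = spearmanr(conc, pct).statistic
        sign = 0 if np.isnan(rho) or rho == 0 else int(np.sign(rho))
    ic50 = None
    for k in range(1, conc.size):
        lo, hi = pct[k - 1], pct[k]
        if (lo - 50.0) * (hi - 50.0) <= 0 and lo != hi:
            ic50 = float(conc[k - 1] + (50.0 - lo) * (conc[k] - conc[k - 1]) / (hi - lo))
            break
        if lo == 50.0:
            ic50 = float(conc[k - 1])
            break
    return DoseResponseSummary(
        assay=s.assay,
        max_inhibition_pct=float(pct[imax]),
        conc_at_max=float(conc[imax]),
        monotonicity_sign=sign,
        ic50_interp=ic50,
    )


def mean_with_propagated_sd(
    abs_sample: Sequence[float],
    abs_control: Sequence[float],
    abs_blank: Sequence[float],
    assay: Assay = Assay.UPTAKE,
) -> tuple[float, float]:
    """Inhibition of replicate means, with SD by first-order propagation.

    Technical replicates are averaged per role before the formula; the SD of
    the percent value follows from the replicate SDs via the gradient of
    R = 100*(AC - AS)/(AC - AB).
    """
    as_, ac, ab = (np.asarray(x, dtype=float) for x in (abs_sample, abs_control, abs_blank))
    m = InhibitionMeasurement(
        assay=assay, abs_sample_as=float(as_.mean()),
        abs_control_ac=float(ac.mean()), abs_blank_ab=float(ab.mean()),
    )
    value = inhibition_rate(m)
    window = m.abs_control_ac - m.abs_blank_ab
    d_as = -100.0 / window
    d_ac = 100.0 * (m.abs_sample_as - m.abs_blank_ab) / window**2
    d_ab = 100.0 * (m.abs_control_ac - m.abs_sample_as) / window**2
    var = 0.0
    for deriv, arr in ((d_as, as_), (d_ac, ac), (d_ab, ab)):
        if arr.size > 1:
            var += deriv**2 * arr.var(ddof=1)
    return value, float(np.sqrt(var))
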