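"""Apparent-permeability estimation from transwell time courses.

A transwell experiment places a donor solution on one side of a cell
monolayer (apical for AP->BL, basolateral for BL->AP) and measures solute
appearing in the receiver chamber over time.  Under sink conditions
(receiver concentration <= 10% of the donor concentration) the flux is
approximately constant and the apparent permeability is

    Papp = (dQ/dt) / (A * C0)        [cm/s]

where Q is the cumulative receiver-side amount, A the membrane area (cm^2)
and C0 the initial donor concentration.  Once the receiver concentration
exceeds 10% of the donor side, back-diffusion matters and Papp is instead
obtained by fitting the two-compartment relaxation

    C_R(t) = Ceq + (C_R0 - Ceq) * exp(-Papp * A * (1/V_R + 1/V_D) * t)

with Ceq = M_tot / (V_D + V_R) and M_tot = C0*V_D + C_R0*V_R.

Periodic sampling withdraws a volume V_S from the receiver and replaces it
with blank medium; all quantities here correct for that withdrawal, either
by adding the withdrawn mass back (``cumulative_transported``) or through
the replacement factor f = 1 - V_S/V_R (``compute_facum``).
"""

from __future__ import annotations

import enum
import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy.optimize import least_squares

__all__ = [
    "Direction",
    "PappMethod",
    "TransportTimeCourse",
    "PappEstimate",
    "DirectionalComparison",
    "cumulative_transported",
    "estimate_papp_sink",
    "compute_facum",
    "fit_papp_nonsink",
    "select_papp",
    "uptake_ratio",
    "percent_of_control",
    "compare_directions",
    "SINK_RECEIVER_FRACTION",
]

#: Receiver/donor concentration ratio above which sink conditions are violated.
SINK_RECEIVER_FRACTION = 0.10


class Direction(str, enum.Enum):
    """Transport direction across the monolayer."""

    AP_BL = "AP_BL"  # apical -> basolateral (absorptive)
    BL_AP = "BL_AP"  # basolateral -> apical (secretory)


class PappMethod(str, enum.Enum):
    SINK_LINEAR = "SINK_LINEAR"
    NONSINK_FIT = "NONSINK_FIT"


class TransportError(ValueError):
    """Invalid transwell data or an unidentifiable fit."""


class TransportTimeCourse(BaseModel):
    """One well's transwell experiment.

    Volumes in cm^3 (mL), area in cm^2, times in seconds, concentrations in
    any consistent amount/cm^3 unit (dpm, mmol, ...).  ``conc_donor_series``
    is optional; when absent the donor concentration is reconstructed by
    mass balance from the receiver-side ledger.
    """

    model_config = ConfigDict(frozen=True)

    direction: Direction = Direction.AP_BL
    area_a: float
    vol_donor_vd: float
    vol_receiver_vr: float
    vol_sample_vs: float = 0.0
    conc_donor_c0: float
    conc_receiver_cr0: float = 0.0
    times: tuple[float, ...]
    conc_receiver: tuple[float, ...]
    conc_donor_series: Optional[tuple[float, ...]] = None
    well_id: str = ""

    @field_validator("times", "conc_receiver", "conc_donor_series", mode="before")
    @classmethod
    def _as_tuple(cls, v):
        if v is None:
            return v
        return tuple(float(x) for x in v)

    @model_validator(mode="after")
    def _validate(self):
        if self.area_a <= 0 or self.vol_donor_vd <= 0 or self.vol_receiver_vr <= 0:
            raise ValueError("area and chamber volumes must be positive")
        if not (0.0 <= self.vol_sample_vs < self.vol_receiver_vr):
            raise ValueError("sampling volume must satisfy 0 <= V_S < V_R")
        if self.conc_donor_c0 < 0 or self.conc_receiver_cr0 < 0:
            raise ValueError("initial concentrations must be non-negative")
        t = np.asarray(self.times, dtype=float)
        if t.size != len(self.conc_receiver):
            raise ValueError("times and conc_receiver must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t.size and t[0] < 0:
            raise ValueError("times must be non-negative")
        if any(c < 0 for c in self.conc_receiver):
            raise ValueError("receiver concentrations must be non-negative")
        if self.conc_donor_series is not None:
            if len(self.conc_donor_series) != t.size:
                raise ValueError("donor series length mismatch")
            if any(c < 0 for c in self.conc_donor_series):
                raise ValueError("donor concentrations must be non-negative")
        return self

    @property
    def replacement_factor(self) -> float:
        """f = 1 - V_S/V_R, in (0, 1]."""
        return 1.0 - self.vol_sample_vs / self.vol_receiver_vr

    @property
    def mtot(self) -> float:
        """Total system mass M_tot = C0*V_D + C_R0*V_R."""
        return self.conc_donor_c0 * self.vol_donor_vd + self.conc_receiver_cr0 * self.vol_receiver_vr

    def donor_concentrations(self) -> np.ndarray:
        """Measured donor series, or mass-balance reconstruction
        C_D(t_k) = (M_tot - Q(t_k)) / V_D when unmeasured."""
        if self.conc_donor_series is not None:
            return np.asarray(self.conc_donor_series, dtype=float)
        q = cumulative_transported(self)
        return (self.mtot - q) / self.vol_donor_vd


class PappEstimate(BaseModel):
    """An apparent-permeability estimate with fit diagnostics."""

    model_config = ConfigDict(frozen=True)

    papp: float
    method: PappMethod
    dqdt: Optional[float] = None
    mtot: Optional[float] = None
    facum: tuple[float, ...] = ()
    r_squared: Optional[float] = None
    sink_violated: bool = False


class DirectionalComparison(BaseModel):
    """Bidirectional summary: uptake ratio and percent-of-control columns."""

    model_config = ConfigDict(frozen=True)

    papp_ap_bl: float
    papp_bl_ap: float
    uptake_ratio: float
    pct_of_control_ap_bl: Optional[float] = None
    pct_of_control_bl_ap: Optional[float] = None


def cumulative_transported(tc: TransportTimeCourse) -> np.ndarray:
    """Cumulative receiver-side amount Q(t_k), sampling mass added back.

    Q(t_k) = C_R(t_k)*V_R + sum_{j<k} C_R(t_j)*V_S: the mass currently in
    the receiver plus everything withdrawn at earlier sampling events
    (each sample removes C_R*V_S and is replaced by blank medium).
    """
    cr = np.asarray(tc.conc_receiver, dtype=float)
    withdrawn = np.concatenate(([0.0], np.cumsum(cr[:-1] * tc.vol_sample_vs))) if cr.size else cr
    return cr * tc.vol_receiver_vr + withdrawn


def _sink_violated(tc: TransportTimeCourse) -> bool:
    if tc.conc_donor_c0 <= 0:
        return False
    return max(tc.conc_receiver) > SINK_RECEIVER_FRACTION * tc.conc_donor_c0


def estimate_papp_sink(tc: TransportTimeCourse) -> PappEstimate:
    """Sink-regime Papp from the OLS slope of Q(t) against time.

    The intercept is left free so a nonzero initial receiver signal is
    absorbed rather than biasing the slope.  Flags ``sink_violated`` when
    any receiver concentration exceeds 10% of C0.
    """
    if len(tc.times) < 3:
        raise TransportError("sink regression needs at least 3 time points")
    if tc.conc_donor_c0 <= 0:
        raise TransportError("C0 must be positive to normalize the flux")
    t = np.asarray(tc.times, dtype=float)
    q = cumulative_transported(tc)
    slope, intercept = np.polyfit(t, q, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((q - pred) ** 2))
    ss_tot = float(np.sum((q - q.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    papp = float(slope) / (tc.area_a * tc.conc_donor_c0)
    return PappEstimate(
        papp=papp,
        method=PappMethod.SINK_LINEAR,
        dqdt=float(slope),
        facum=tuple(compute_facum(tc)),
        r_squared=r2,
        sink_violated=_sink_violated(tc),
    )


def compute_facum(tc: TransportTimeCourse, per_area: bool = False) -> np.ndarray:
    """Cumulative fraction of donor mass transported, FAcum(t_i).

    FAcum(t_i) = sum_{k<=i} [C_R(t_k) - f*C_R(t_{k-1})] * V_R
                 / ( mean(C_D(t_{k-1}), C_D(t_k)) * V_D ),   f = 1 - V_S/V_R.

    Each term is the interval's transported mass (the factor f discounts the
    receiver concentration carried over after sampling replacement) divided
    by the donor mass available over the interval, so the result is the
    dimensionless fraction transported.  ``per_area=True`` instead divides
    by (A * mean C_D), the raw per-area variant (cm^3/cm^2 units).
    """
    cr = np.asarray(tc.conc_receiver, dtype=float)
    if cr.size == 0:
        return np.asarray([])
    cd = tc.donor_concentrations()
    f = tc.replacement_factor
    out = np.zeros(cr.size)
    acc = 0.0
    for k in range(1, cr.size):
        cd_mean = 0.5 * (cd[k - 1] + cd[k])
        if cd_mean <= 0:
            raise TransportError(f"donor concentration non-positive in interval {k}")
        transported = (cr[k] - f * cr[k - 1]) * tc.vol_receiver_vr
        denom = cd_mean * (tc.area_a if per_area else tc.vol_donor_vd)
        acc += transported / denom
        out[k] = acc
    return out


def _nonsink_model(t: np.ndarray, papp: float, tc: TransportTimeCourse) -> np.ndarray:
    ceq = tc.mtot / (tc.vol_donor_vd + tc.vol_receiver_vr)
    rate = papp * tc.area_a * (1.0 / tc.vol_receiver_vr + 1.0 / tc.vol_donor_vd)
    return ceq + (tc.conc_receiver_cr0 - ceq) * np.exp(-rate * t)


def fit_papp_nonsink(tc: TransportTimeCourse) -> PappEstimate:
    """Non-sink Papp by least-squares fit of the two-compartment relaxation.

    Measured receiver concentrations are first corrected to their
    no-sampling equivalent C_R*(t_k) = Q(t_k)/V_R, because the relaxation
    model has no sampling term.  A single bounded parameter (Papp in
    [0, 1] cm/s) is fitted, initialized from the sink estimate (floored at
    1e-9 cm/s); the search is deterministic.
    """
    if len(tc.times) < 3:
        raise TransportError("non-sink fit needs at least 3 time points")
    t = np.asarray(tc.times, dtype=float)
    cr_star = cumulative_transported(tc) / tc.vol_receiver_vr
    ceq = tc.mtot / (tc.vol_donor_vd + tc.vol_receiver_vr)
    scale = max(abs(ceq), float(np.max(np.abs(cr_star))), 1e-300)
    if np.all(np.abs(cr_star - ceq) < 1e-12 * scale):
        raise TransportError("Papp unidentifiable: all points at the equilibrium value")

    try:
        x0 = max(estimate_papp_sink(tc).papp, 1e-9)
    except TransportError:
        x0 = 1e-9
    x0 = min(x0, 1.0)

    def resid(p):
        return _nonsink_model(t, p[0], tc) - cr_star

    sol = least_squares(
        resid, x0=[x0], bounds=(0.0, 1.0), xtol=1e-14, ftol=1e-15, gtol=1e-15,
        max_nfev=500,
    )
    if not sol.success:
        raise TransportError(f"non-sink fit did not converge: {sol.message}")
    papp = float(sol.x[0])
    pred = _nonsink_model(t, papp, tc)
    ss_res = float(np.sum((cr_star - pred) ** 2))
    ss_tot = float(np.sum((cr_star - cr_star.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return PappEstimate(
        papp=papp,
        method=PappMethod.NONSINK_FIT,
        mtot=tc.mtot,
        facum=tuple(compute_facum(tc)),
        r_squared=r2,
        sink_violated=_sink_violated(tc),
    )


def select_papp(tc: TransportTimeCourse) -> PappEstimate:
    """Sink regression while max C_R <= 10% of C0 (boundary inclusive),
    non-sink relaxation fit once the receiver concentration exceeds it."""
    if _sink_violated(tc):
        return fit_papp_nonsink(tc)
    return estimate_papp_sink(tc)


def uptake_ratio(papp_ap_bl: float, papp_bl_ap: float) -> float:
    """UR = Papp(AP->BL) / Papp(BL->AP): absorptive over secretory permeability."""
    if papp_bl_ap <= 0:
        raise TransportError("BL->AP Papp must be positive for an uptake ratio")
    return papp_ap_bl / papp_bl_ap


def percent_of_control(papp_sample: float, papp_control: float) -> float:
    """Sample permeability as a percentage of the matched control well."""
    if papp_control <= 0:
        raise TransportError("control Papp must be positive")
    return 100.0 * papp_sample / papp_control


def compare_directions(
    papp_ap_bl: float,
    papp_bl_ap: float,
    control_ap_bl: Optional[float] = None,
    control_bl_ap: Optional[float] = None,
) -> DirectionalComparison:
    """Bundle the bidirectional summary used in permeability report tables."""
    return DirectionalComparison(
        papp_ap_bl=papp_ap_bl,
        papp_bl_ap=papp_bl_ap,
        uptake_ratio=uptake_ratio(papp_ap_bl, papp_bl_ap),
        pct_of_control_ap_bl=(
            percent_of_control(papp_ap_bl, control_ap_bl) if control_ap_bl is not None else None
        ),
        pct_of_control_bl_ap=(
            percent_of_control(papp_bl_ap, control_bl_ap) if control_bl_ap is not None else None
        ),
    )
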