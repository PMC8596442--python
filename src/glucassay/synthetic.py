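"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* ``simulate_transport`` — two-compartment passive diffusion across a
  transwell membrane at a chosen true Papp, with periodic sampling
  withdrawal and blank-medium replacement.  Between sampling events the
  exact exponential relaxation is used (not numerical stepping), so
  noiseless recovery can be asserted at machine precision; each event
  withdraws C_R*V_S of mass and restores the volume with blank medium.
  A hidden ledger tracks donor, receiver and withdrawn mass, which must
  sum to M_tot exactly.

* ``simulate_plate`` — plate absorbances consistent with a chosen true
  inhibition fraction (the inverse of the inhibition formula):
  AS = AC - (p/100)*(AC - AB) + noise.

* ``simulate_panels`` — group-structured metabolic panels with stated
  means/SDs, Gaussian draws truncated at zero.

Defaults mirror the 12-well transwell glucose assay this package targets:
A = 1.13 cm^2 (12-mm insert), V_D = 0.5 mL donor, V_R = 1.5 mL receiver,
100 uL samples at 0/30/60/90/120 min, and four animal groups of n = 8 with
the disease-model fasting glucose at 23.05 +/- 5.03 mmol/L.

Measurement noise is multiplicative Gaussian (CV-parameterized, truncated
at zero) for concentrations and additive for absorbances.  A single integer
seed deterministically derives independent substreams.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .inhibition import Assay, InhibitionMeasurement
from .metabolic import ANALYTES, Group, MetabolicPanel
from .transport import Direction, TransportTimeCourse

__all__ = [
    "TransportSimConfig",
    "PlateSimConfig",
    "TransportSimResult",
    "simulate_transport",
    "simulate_plate",
    "simulate_panels",
    "DEFAULT_GROUP_MEANS",
    "DEFAULT_GROUP_SDS",
]

# 0, 30, 60, 90, 120 min in seconds
DEFAULT_SAMPLE_TIMES = (0.0, 1800.0, 3600.0, 5400.0, 7200.0)


class TransportSimConfig(BaseModel):
    """Ground-truth parameters for one simulated transwell course."""

    model_config = ConfigDict(frozen=True)

    papp_true: float  # cm/s
    area_a: float = 1.13  # cm^2, 12-mm insert
    vol_donor_vd: float = 0.5  # cm^3
    vol_receiver_vr: float = 1.5  # cm^3
    vol_sample_vs: float = 0.1  # cm^3 per sampling event
    conc_donor_c0: float = 50.0  # amount/cm^3 (50 mmol/L glucose)
    conc_receiver_cr0: float = 0.0
    sample_times: tuple[float, ...] = DEFAULT_SAMPLE_TIMES
    noise_cv: float = 0.0
    direction: Direction = Direction.AP_BL
    include_donor_series: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self):
        if self.papp_true < 0:
            raise ValueError("papp_true must be non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        t = np.asarray(self.sample_times, dtype=float)
        if t.size == 0 or (t.size > 1 and np.any(np.diff(t) <= 0)) or t[0] < 0:
            raise ValueError("sample_times must be non-empty, non-negative, strictly increasing")
        if self.area_a <= 0 or self.vol_donor_vd <= 0 or self.vol_receiver_vr <= 0:
            raise ValueError("geometry must be positive")
        if not (0.0 <= self.vol_sample_vs < self.vol_receiver_vr):
            raise ValueError("0 <= V_S < V_R required")
        if self.conc_donor_c0 < 0 or self.conc_receiver_cr0 < 0:
            raise ValueError("initial concentrations must be non-negative")
        return self


class PlateSimConfig(BaseModel):
    """Ground truth for a simulated inhibition plate."""

    model_config = ConfigDict(frozen=True)

    true_inhibition_pct: float
    abs_control: float = 1.0
    abs_blank: float = 0.2
    noise_sd: float = 0.0
    replicates: int = 3
    assay: Assay = Assay.UPTAKE
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self):
        if self.abs_control == self.abs_blank:
            raise ValueError("abs_control must differ from abs_blank")
        if self.abs_control < 0 or self.abs_blank < 0:
            raise ValueError("absorbances must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        return self


class TransportSimResult(BaseModel):
    """A simulated course plus its conservation ledger and hidden truth.

    ``ledger`` rows (one per sampling event) carry the true donor mass,
    receiver mass and cumulative withdrawn mass immediately before the
    event's withdrawal; their sum equals M_tot exactly.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    timecourse: TransportTimeCourse
    papp_true: float
    donor_mass: tuple[float, ...]
    receiver_mass: tuple[float, ...]
    withdrawn_mass: tuple[float, ...]
    true_conc_receiver: tuple[float, ...]

    @property
    def ledger(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.timecourse.times,
                "donor_mass": self.donor_mass,
                "receiver_mass": self.receiver_mass,
                "withdrawn_mass": self.withdrawn_mass,
            }
        )

    @property
    def mtot(self) -> float:
        return self.timecourse.mtot


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_transport(cfg: TransportSimConfig) -> TransportSimResult:
    """Simulate one transwell course with exact interval dynamics.

    Between sampling events both chambers relax exponentially toward the
    current equilibrium (M/(V_D+V_R)) at rate Papp*A*(1/V_R + 1/V_D).  At
    each sample time the pre-withdrawal receiver concentration is recorded
    (with multiplicative noise when noise_cv > 0), then V_S*C_R of mass is
    withdrawn and the volume replaced with blank medium.
    """
    (rng,) = _rng_streams(cfg.seed, 1)
    rate = cfg.papp_true * cfg.area_a * (1.0 / cfg.vol_receiver_vr + 1.0 / cfg.vol_donor_vd)
    cd, cr = cfg.conc_donor_c0, cfg.conc_receiver_cr0
    withdrawn = 0.0
    t_prev = 0.0
    times = np.asarray(cfg.sample_times, dtype=float)

    true_cr, meas_cr, meas_cd = [], [], []
    donor_mass, receiver_mass, withdrawn_mass = [], [], []
    for t in times:
        dt = t - t_prev
        if dt > 0:
            m_in_play = cd * cfg.vol_donor_vd + cr * cfg.vol_receiver_vr
            ceq = m_in_play / (cfg.vol_donor_vd + cfg.vol_receiver_vr)
            cr = ceq + (cr - ceq) * np.exp(-rate * dt)
            cd = (m_in_play - cr * cfg.vol_receiver_vr) / cfg.vol_donor_vd
        t_prev = t

        true_cr.append(cr)
        donor_mass.append(cd * cfg.vol_donor_vd)
        receiver_mass.append(cr * cfg.vol_receiver_vr)
        withdrawn_mass.append(withdrawn)
        if cfg.noise_cv > 0:
            meas_cr.append(max(0.0, cr * (1.0 + cfg.noise_cv * rng.standard_normal())))
            meas_cd.append(max(0.0, cd * (1.0 + cfg.noise_cv * rng.standard_normal())))
        else:
            meas_cr.append(cr)
            meas_cd.append(cd)

        # sampling event: withdraw V_S of receiver fluid, refill with blank
        withdrawn += cr * cfg.vol_sample_vs
        cr *= 1.0 - cfg.vol_sample_vs / cfg.vol_receiver_vr

    tc = TransportTimeCourse(
        direction=cfg.direction,
        area_a=cfg.area_a,
        vol_donor_vd=cfg.vol_donor_vd,
        vol_receiver_vr=cfg.vol_receiver_vr,
        vol_sample_vs=cfg.vol_sample_vs,
        conc_donor_c0=cfg.conc_donor_c0,
        conc_receiver_cr0=cfg.conc_receiver_cr0,
        times=tuple(times),
        conc_receiver=tuple(meas_cr),
        conc_donor_series=tuple(meas_cd) if cfg.include_donor_series else None,
    )
    return TransportSimResult(
        timecourse=tc,
        papp_true=cfg.papp_true,
        donor_mass=tuple(donor_mass),
        receiver_mass=tuple(receiver_mass),
        withdrawn_mass=tuple(withdrawn_mass),
        true_conc_receiver=tuple(true_cr),
    )


def simulate_plate(cfg: PlateSimConfig) -> list[InhibitionMeasurement]:
    """Plate absorbances whose noiseless inhibition is exactly the truth.

    AS = AC - (p/100)*(AC - AB) + N(0, noise_sd), truncated at zero, one
    measurement per replicate; control and blank wells are noise-free
    anchors so the round trip is exact when noise_sd = 0.
    """
    (rng,) = _rng_streams(cfg.seed, 1)
    # convex combination rather than AC - w*(AC-AB): the p=0 and p=100
    # endpoints then equal AC and AB exactly in floating point
    w = cfg.true_inhibition_pct / 100.0
    as_true = cfg.abs_control * (1.0 - w) + cfg.abs_blank * w
    out = []
    for _ in range(cfg.replicates):
        as_obs = as_true + (cfg.noise_sd * rng.standard_normal() if cfg.noise_sd > 0 else 0.0)
        out.append(
            InhibitionMeasurement(
                assay=cfg.assay,
                abs_sample_as=max(0.0, as_obs),
                abs_control_ac=cfg.abs_control,
                abs_blank_ab=cfg.abs_blank,
            )
        )
    return out


# Group conditions for the four-arm animal study the panels emulate.
# Disease-model FBG 23.05 +/- 5.03 mmol/L; treated-group FBG means embody
# 34.06% / 37.87% reductions vs the model mean; LDL/HDL group means sit at
# ratios 0.13 / 0.169 / 0.1184 / 0.044.  See docs/methods.md.
DEFAULT_GROUP_MEANS: dict[Group, dict[str, float]] = {
    Group.CONTROL: {"fbg": 6.5, "insulin": 8.0, "tc": 3.0, "tg": 1.0,
                    "ldl": 0.26, "hdl": 2.0, "gsp": 2.0},
    Group.MODEL: {"fbg": 23.05, "insulin": 15.0, "tc": 6.5, "tg": 2.2,
                  "ldl": 0.4394, "hdl": 2.6, "gsp": 3.5},
    Group.PPS_L: {"fbg": 15.20, "insulin": 12.0, "tc": 5.0, "tg": 1.8,
                  "ldl": 0.26048, "hdl": 2.2, "gsp": 3.0},
    Group.PPS_H: {"fbg": 14.32, "insulin": 10.0, "tc": 4.2, "tg": 1.5,
                  "ldl": 0.1012, "hdl": 2.3, "gsp": 2.8},
}

DEFAULT_GROUP_SDS: dict[Group, dict[str, float]] = {
    Group.CONTROL: {"fbg": 0.5, "insulin": 1.5, "tc": 0.3, "tg": 0.15,
                    "ldl": 0.04, "hdl": 0.2, "gsp": 0.2},
    Group.MODEL: {"fbg": 5.03, "insulin": 3.0, "tc": 0.8, "tg": 0.4,
                  "ldl": 0.08, "hdl": 0.3, "gsp": 0.4},
    Group.PPS_L: {"fbg": 3.0, "insulin": 2.5, "tc": 0.6, "tg": 0.3,
                  "ldl": 0.05, "hdl": 0.25, "gsp": 0.3},
    Group.PPS_H: {"fbg": 3.0, "insulin": 2.0, "tc": 0.5, "tg": 0.25,
                  "ldl": 0.03, "hdl": 0.25, "gsp": 0.3},
}


def simulate_panels(
    group_means: Optional[Mapping[Group, Mapping[str, float]]] = None,
    group_sds: Optional[Mapping[Group, Mapping[str, float]]] = None,
    n_per_group: int = 8,
    seed: int = 0,
    week: int = 4,
) -> list[MetabolicPanel]:
    """Group-structured panels: independent Gaussian draws truncated at 0."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    means = group_means if group_means is not None else DEFAULT_GROUP_MEANS
    sds = group_sds if group_sds is not None else DEFAULT_GROUP_SDS
    streams = _rng_streams(seed, len(means))
    panels = []
    for rng, (group, analyte_means) in zip(streams, means.items()):
        analyte_sds = sds.get(group, {})
        for i in range(n_per_group):
            values = {}
            for analyte, mu in analyte_means.items():
                if analyte not in ANALYTES:
                    raise ValueError(f"unknown analyte {analyte!r}")
                sd = analyte_sds.get(analyte, 0.0)
                if sd < 0:
                    raise ValueError("SDs must be non-negative")
                values[analyte] = max(0.0, mu + sd * rng.standard_normal())
            panels.append(
                MetabolicPanel(
                    subject_id=f"{Group(group).value}_{i + 1:02d}",
                    group=Group(group),
                    week=week,
                    **values,
                )
            )
    return panels
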