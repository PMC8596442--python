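"""Extraction-chain bookkeeping and GC monosaccharide molar ratios.

Yield, retention and protein-removal percentages for a sequential
polysaccharide extraction (crude -> alcohol-precipitated -> deproteinized
-> column-refined fractions), plus area-normalization of gas-chromatography
peaks into monosaccharide molar ratios relative to a reference sugar.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "CompositionRecord",
    "GCPeak",
    "GCPeakTable",
    "extraction_yield",
    "retention_rate",
    "protein_removal_rate",
    "molar_ratios_from_gc",
    "assign_peaks",
]


class CompositionError(ValueError):
    pass


class CompositionRecord(BaseModel):
    """Masses/contents along one step of the extraction chain."""

    model_config = ConfigDict(frozen=True)

    mass_product: Optional[float] = None  # g
    mass_input: Optional[float] = None  # g
    protein_before: Optional[float] = None  # ug/mL
    protein_after: Optional[float] = None  # ug/mL
    carbohydrate_content: Optional[float] = None  # g/100 g

    @model_validator(mode="after")
    def _validate(self):
        for name in ("mass_product", "mass_input"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("protein_before", "protein_after", "carbohydrate_content"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        return self


class GCPeak(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str  # empty string when unassigned
    retention_time: float  # min
    area: float  # arbitrary detector units

    @model_validator(mode="after")
    def _validate(self):
        if self.area <= 0:
            raise ValueError("peak area must be positive")
        return self


class GCPeakTable(BaseModel):
    """Integrated GC peaks with an internal standard and a reference sugar.

    ``response_factors`` map sugar name -> area per mole (default 1:
    pure area normalization); the reference sugar's molar ratio is 1.
    """

    model_config = ConfigDict(frozen=True)

    peaks: tuple[GCPeak, ...]
    reference_sugar: str
    internal_standard: Optional[tuple[str, float, float]] = None  # (name, mg, area)
    response_factors: Mapping[str, float] = {}

    @model_validator(mode="after")
    def _validate(self):
        names = {p.name for p in self.peaks}
        if self.reference_sugar not in names:
            raise ValueError(f"reference sugar {self.reference_sugar!r} not among peaks")
        for name, rf in self.response_factors.items():
            if rf <= 0:
                raise ValueError(f"response factor for {name!r} must be positive")
        return self


def extraction_yield(r: CompositionRecord) -> float:
    """Extraction yield (%, w/w) = 100 * product mass / input mass."""
    if r.mass_product is None or r.mass_input is None:
        raise CompositionError("extraction_yield needs mass_product and mass_input")
    return 100.0 * r.mass_product / r.mass_input


def retention_rate(r: CompositionRecord) -> float:
    """Polysaccharide retention (%) across a purification step.

    Same functional as ``extraction_yield`` (product over input mass);
    named separately because the field reports the two quantities under
    different names at different chain steps.
    """
    return extraction_yield(r)


def protein_removal_rate(r: CompositionRecord) -> float:
    """Protein removal (%) = 100 * (before - after) / before."""
    if r.protein_before is None or r.protein_after is None:
        raise CompositionError("protein_removal_rate needs protein_before and protein_after")
    if r.protein_before <= 0:
        raise CompositionError("protein_before must be positive")
    return 100.0 * (r.protein_before - r.protein_after) / r.protein_before


def molar_ratios_from_gc(t: GCPeakTable) -> dict[str, float]:
    """Monosaccharide molar ratios by area normalization.

    mole_i = area_i / response_factor_i, ratio_i = mole_i / mole_reference;
    the reference sugar's ratio is exactly 1.  Report layers round to 1 d.p.
    """
    moles: dict[str, float] = {}
    for p in t.peaks:
        if not p.name:
            continue
        rf = t.response_factors.get(p.name, 1.0)
        moles[p.name] = moles.get(p.name, 0.0) + p.area / rf
    ref = moles.get(t.reference_sugar)
    if ref is None or ref <= 0:
        raise CompositionError("reference sugar must have positive total area")
    return {name: mole / ref for name, mole in moles.items()}


def assign_peaks(
    peaks: Sequence[GCPeak],
    standards: Mapping[str, float],
    window: float = 0.3,
) -> tuple[tuple[GCPeak, ...], tuple[GCPeak, ...]]:
    """Assign unnamed peaks to the nearest standard retention time.

    A peak matches the closest standard within ``window`` minutes; already
    named peaks pass through untouched.  Returns (assigned, unmatched) —
    unmatched peaks are reported, never silently dropped.
    """
    assigned: list[GCPeak] = []
    unmatched: list[GCPeak] = []
    for p in peaks:
        if p.name:
            assigned.append(p)
            continue
        best_name, best_dt = None, window
        for name, rt in standards.items():
            dt = abs(p.retention_time - rt)
            if dt <= best_dt:
                best_name, best_dt = name, dt
        if best_name is None:
            unmatched.append(p)
        else:
            assigned.append(GCPeak(name=best_name, retention_time=p.retention_time, area=p.area))
    return tuple(assigned), tuple(unmatched)
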