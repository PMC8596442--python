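"""CSV schemas, rounding and report writing.

All tabular I/O is UTF-8 comma-separated CSV with a mandatory header row
and "." decimal separator.  Presentation rounding is half-up (decimal
module), applied only at the report layer; machine-readable JSON keeps full
precision.

Schemas
-------
transport time course : well_id, direction, time, conc_receiver[, conc_donor]
well metadata         : well_id, area, vol_donor, vol_receiver, vol_sample,
                        conc_donor_c0, conc_receiver_cr0[, time_unit s|min]
plate                 : well, assay, role {sample,control,blank,background},
                        concentration, absorbance, replicate
GC peaks              : name (may be blank), retention_time, area
GC standards          : name, retention_time
metabolic panels      : subject_id, group, week, fbg, insulin, tc, tg, ldl,
                        hdl, gsp
"""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import GCPeak
from .inhibition import Assay, mean_with_propagated_sd
from .metabolic import ANALYTES, Group, MetabolicPanel
from .transport import Direction, TransportTimeCourse

__all__ = [
    "SchemaError",
    "round_half_up",
    "read_timecourses",
    "write_timecourses",
    "read_plate",
    "summarize_plate",
    "read_gc_peaks",
    "read_gc_standards",
    "read_panels",
    "write_panels",
    "write_report",
]


class SchemaError(ValueError):
    """A file does not conform to its CSV schema."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (table presentation convention).

    7.6346 -> 7.63, 2.635 -> 2.64; distinct from banker's rounding.
    """
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_timecourses(timecourse_path, wells_path) -> list[TransportTimeCourse]:
    """Read per-well time courses plus well metadata into validated records.

    Times flagged ``time_unit=min`` in the metadata are converted to
    seconds.  Malformed rows are reported with their row number.
    """
    tc_df = pd.read_csv(timecourse_path)
    wells_df = pd.read_csv(wells_path)
    _require_columns(tc_df, ["well_id", "direction", "time", "conc_receiver"], timecourse_path)
    _require_columns(
        wells_df,
        ["well_id", "area", "vol_donor", "vol_receiver", "vol_sample",
         "conc_donor_c0", "conc_receiver_cr0"],
        wells_path,
    )
    for i, row in tc_df.iterrows():
        if pd.notna(row["conc_receiver"]) and float(row["conc_receiver"]) < 0:
            raise SchemaError(
                f"{timecourse_path}: row {i + 2}: negative conc_receiver "
                f"({row['conc_receiver']}) for well {row['well_id']}"
            )
    wells = wells_df.set_index("well_id")
    out = []
    for well_id, sub in tc_df.groupby("well_id", sort=True):
        if well_id not in wells.index:
            raise SchemaError(f"{timecourse_path}: well {well_id!r} missing from {wells_path}")
        meta = wells.loc[well_id]
        sub = sub.sort_values("time")
        times = sub["time"].to_numpy(dtype=float)
        unit = str(meta.get("time_unit", "s") if pd.notna(meta.get("time_unit", "s")) else "s")
        if unit == "min":
            times = times * 60.0
        elif unit not in ("s", "sec", "seconds"):
            raise SchemaError(f"{wells_path}: unknown time_unit {unit!r} for well {well_id}")
        donor = None
        if "conc_donor" in sub.columns and sub["conc_donor"].notna().all():
            donor = tuple(sub["conc_donor"].astype(float))
        try:
            out.append(
                TransportTimeCourse(
                    well_id=str(well_id),
                    direction=Direction(str(sub["direction"].iloc[0])),
                    area_a=float(meta["area"]),
                    vol_donor_vd=float(meta["vol_donor"]),
                    vol_receiver_vr=float(meta["vol_receiver"]),
                    vol_sample_vs=float(meta["vol_sample"]),
                    conc_donor_c0=float(meta["conc_donor_c0"]),
                    conc_receiver_cr0=float(meta["conc_receiver_cr0"]),
                    times=tuple(times),
                    conc_receiver=tuple(sub["conc_receiver"].astype(float)),
                    conc_donor_series=donor,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{timecourse_path}: well {well_id!r}: {exc}") from exc
    return out


def write_timecourses(tcs: Iterable[TransportTimeCourse], timecourse_path, wells_path) -> None:
    """Inverse of ``read_timecourses`` (canonical seconds, full precision)."""
    tc_rows, well_rows = [], []
    for tc in tcs:
        donor = tc.conc_donor_series
        for k, (t, cr) in enumerate(zip(tc.times, tc.conc_receiver)):
            row = {"well_id": tc.well_id, "direction": tc.direction.value,
                   "time": t, "conc_receiver": cr}
            if donor is not None:
                row["conc_donor"] = donor[k]
            tc_rows.append(row)
        well_rows.append(
            {"well_id": tc.well_id, "area": tc.area_a, "vol_donor": tc.vol_donor_vd,
             "vol_receiver": tc.vol_receiver_vr, "vol_sample": tc.vol_sample_vs,
             "conc_donor_c0": tc.conc_donor_c0, "conc_receiver_cr0": tc.conc_receiver_cr0,
             "time_unit": "s"}
        )
    pd.DataFrame(tc_rows).to_csv(timecourse_path, index=False)
    pd.DataFrame(well_rows).to_csv(wells_path, index=False)


def read_plate(path) -> pd.DataFrame:
    """Read a plate CSV and validate roles/assays."""
    df = pd.read_csv(path)
    _require_columns(df, ["well", "assay", "role", "concentration", "absorbance", "replicate"], path)
    valid_roles = {"sample", "control", "blank", "background"}
    for i, row in df.iterrows():
        if row["role"] not in valid_roles:
            raise SchemaError(f"{path}: row {i + 2}: unknown role {row['role']!r}")
        try:
            Assay(str(row["assay"]))
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i + 2}: unknown assay {row['assay']!r}") from exc
        if float(row["absorbance"]) < 0:
            raise SchemaError(f"{path}: row {i + 2}: negative absorbance")
    return df


def summarize_plate(df: pd.DataFrame) -> pd.DataFrame:
    """Tidy percent-inhibition table per (assay, concentration) with SD.

    Control and blank replicates are shared within an assay; sample
    replicates are grouped by concentration.  Replicates are averaged per
    role before the formula; the SD column is first-order propagated.
    """
    out = []
    for assay_name, sub in df.groupby("assay", sort=True):
        controls = sub.loc[sub["role"] == "control", "absorbance"].to_numpy(dtype=float)
        blanks = sub.loc[sub["role"] == "blank", "absorbance"].to_numpy(dtype=float)
        if controls.size == 0:
            raise SchemaError(f"assay {assay_name!r}: no control wells")
        if blanks.size == 0:
            blanks = np.asarray([0.0])
        samples = sub[sub["role"] == "sample"]
        for conc, wells in samples.groupby("concentration", sort=True):
            value, sd = mean_with_propagated_sd(
                wells["absorbance"].to_numpy(dtype=float), controls, blanks,
                assay=Assay(str(assay_name)),
            )
            out.append(
                {"assay": assay_name, "concentration": conc,
                 "inhibition_pct": value, "inhibition_sd": sd,
                 "n_replicates": len(wells)}
            )
    return pd.DataFrame(out)


def read_gc_peaks(path) -> list[GCPeak]:
    df = pd.read_csv(path)
    _require_columns(df, ["name", "retention_time", "area"], path)
    peaks = []
    for i, row in df.iterrows():
        name = "" if pd.isna(row["name"]) else str(row["name"])
        try:
            peaks.append(GCPeak(name=name, retention_time=float(row["retention_time"]),
                                area=float(row["area"])))
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return peaks


def read_gc_standards(path) -> dict[str, float]:
    df = pd.read_csv(path)
    _require_columns(df, ["name", "retention_time"], path)
    return {str(r["name"]): float(r["retention_time"]) for _, r in df.iterrows()}


def read_panels(path) -> list[MetabolicPanel]:
    df = pd.read_csv(path)
    _require_columns(df, ["subject_id", "group"], path)
    panels = []
    for i, row in df.iterrows():
        values = {a: (float(row[a]) if a in df.columns and pd.notna(row[a]) else None)
                  for a in ANALYTES}
        try:
            panels.append(
                MetabolicPanel(
                    subject_id=str(row["subject_id"]),
                    group=Group(str(row["group"])),
                    week=int(row["week"]) if "week" in df.columns and pd.notna(row.get("week")) else 0,
                    **values,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return panels


def write_panels(panels: Iterable[MetabolicPanel], path) -> None:
    rows = [
        {"subject_id": p.subject_id, "group": p.group.value, "week": p.week,
         **{a: getattr(p, a) for a in ANALYTES}}
        for p in panels
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _render(df: pd.DataFrame, precision: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: f"{round_half_up(v, precision):.{precision}f}" if pd.notna(v) else ""
            )
    return out


def write_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    precision: int = 2,
    extra_json: Mapping | None = None,
) -> dict:
    """Write report CSVs (half-up at ``precision``) plus a JSON manifest.

    Deterministic: same tables and config produce byte-identical files.
    The manifest lists every file with its sha256 content hash; full
    numeric precision goes into ``report.json`` alongside the rendered CSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"precision": precision, "files": {}}
    full = {}
    for name, df in sorted(tables.items()):
        path = out_dir / f"{name}.csv"
        _render(df, precision).to_csv(path, index=False, lineterminator="\n")
        manifest["files"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        full[name] = df.to_dict(orient="records")
    report = {"tables": full}
    if extra_json:
        report.update(extra_json)
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")
    manifest["files"][report_path.name] = hashlib.sha256(report_path.read_bytes()).hexdigest()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
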