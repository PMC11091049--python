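"""CSV readers/writers for paired meal-test cohorts.

Input layout (long format)
--------------------------
Measurements CSV, one row per (subject, arm, time):

    subject_id, arm, time_min,
    glucose, glucose_unit, insulin, insulin_unit, cpeptide, cpeptide_unit

``arm`` is ``MT`` or ``MT_I``.  Units may be canonical (``mg/dL``,
``pmol/L``) or assay units (``mmol/L``, ``uU/mL``, ``ng/mL``); conversion
uses a :class:`~insep.units.UnitConversionTable`.  An empty cell drops that
time from that analyte's series only.

Demographics CSV, one row per subject:

    subject_id, sex, age_y, weight_kg, bmi, height_m (optional), dose_U, category
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Optional, Union

import numpy as np
import pandas as pd

from .datamodel import ANALYTES, ARMS, AnalyteSeries, MealTestDataset, SubjectRecord
from .errors import SchemaError, ValidationError
from .units import DEFAULT_UNITS, UnitConversionTable

_MEAS_COLUMNS = [
    "subject_id", "arm", "time_min",
    "glucose", "glucose_unit", "insulin", "insulin_unit", "cpeptide", "cpeptide_unit",
]
_DEMO_COLUMNS = ["subject_id", "sex", "age_y", "weight_kg", "bmi", "dose_U"]

CANONICAL_UNIT = {"glucose": "mg/dL", "insulin": "pmol/L", "cpeptide": "pmol/L"}


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def load_demographics(path: Union[str, Path]) -> dict:
    """Read the demographics CSV into ``{subject_id: SubjectRecord}``."""
    df = pd.read_csv(path)
    _require_columns(df, _DEMO_COLUMNS, f"demographics {path}")
    records = {}
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        height = row.get("height_m", np.nan)
        dose = row["dose_U"]
        records[sid] = SubjectRecord(
            subject_id=sid,
            sex=str(row["sex"]).lower(),
            age=float(row["age_y"]),
            weight=float(row["weight_kg"]),
            bmi=float(row["bmi"]),
            height=None if pd.isna(height) else float(height),
            dose_U=None if pd.isna(dose) else float(dose),
            category=str(row.get("category", "normal")),
        )
    return records


def load_cohort(
    measurements_csv: Union[str, Path],
    demographics_csv: Union[str, Path],
    units: UnitConversionTable = DEFAULT_UNITS,
) -> List[MealTestDataset]:
    """Read a cohort, converting all concentrations to canonical units.

    Returns one :class:`MealTestDataset` per (subject, arm) pair, sorted by
    subject then arm.
    """
    subjects = load_demographics(demographics_csv)
    df = pd.read_csv(measurements_csv)
    _require_columns(df, _MEAS_COLUMNS, f"measurements {measurements_csv}")

    datasets: List[MealTestDataset] = []
    for (sid, arm), grp in df.groupby(["subject_id", "arm"], sort=True):
        sid = str(sid)
        if arm not in ARMS:
            raise ValidationError(f"subject {sid}: unknown arm {arm!r} (expected one of {ARMS})")
        if sid not in subjects:
            raise SchemaError(f"subject {sid} appears in measurements but not in demographics")
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"subject {sid} arm {arm}: non-monotone time_min values")
        series = {}
        for analyte in ANALYTES:
            vals = pd.to_numeric(grp[analyte], errors="coerce").to_numpy(dtype=float)
            keep = ~np.isnan(vals)
            unit_col = grp[f"{analyte}_unit"].astype(str).to_numpy()
            conv = np.array([units.factor(analyte, u) for u in unit_col])
            values = vals[keep] * conv[keep]
            if np.any(values < 0):
                raise ValidationError(f"subject {sid} arm {arm}: negative {analyte} concentration")
            try:
                series[analyte] = AnalyteSeries(
                    analyte=analyte,
                    times=times[keep],
                    values=values,
                    source_unit=unit_col[keep][0] if keep.any() else "",
                )
            except ValidationError as exc:
                raise ValidationError(f"subject {sid} arm {arm}: {exc}") from None
        datasets.append(MealTestDataset(subject=subjects[sid], arm=arm, **series))
    return datasets


def write_cohort(
    datasets: Iterable[MealTestDataset],
    measurements_csv: Union[str, Path],
    demographics_csv: Union[str, Path],
    manifest_json: Optional[Union[str, Path]] = None,
) -> None:
    """Write a cohort back to the long CSV layout, in canonical units."""
    datasets = list(datasets)
    rows = []
    for ds in datasets:
        grid = sorted(set(np.concatenate([ds.glucose.times, ds.insulin.times, ds.cpeptide.times])))
        lookup = {
            a: dict(zip(getattr(ds, a).times, getattr(ds, a).values)) for a in ANALYTES
        }
        for t in grid:
            rows.append({
                "subject_id": ds.subject.subject_id,
                "arm": ds.arm,
                "time_min": t,
                **{a: lookup[a].get(t, np.nan) for a in ANALYTES},
                **{f"{a}_unit": CANONICAL_UNIT[a] for a in ANALYTES},
            })
    pd.DataFrame(rows, columns=_MEAS_COLUMNS).to_csv(measurements_csv, index=False)

    seen = {}
    for ds in datasets:
        seen[ds.subject.subject_id] = ds.subject
    demo_rows = [
        {
            "subject_id": s.subject_id,
            "sex": s.sex,
            "age_y": s.age,
            "weight_kg": s.weight,
            "bmi": s.bmi,
            "height_m": s.height if s.height is not None else "",
            "dose_U": s.dose_U if s.dose_U is not None else "",
            "category": s.category,
        }
        for s in seen.values()
    ]
    pd.DataFrame(demo_rows).to_csv(demographics_csv, index=False)

    if manifest_json is not None:
        manifest = cohort_manifest(datasets)
        Path(manifest_json).write_text(json.dumps(manifest, indent=2))


def cohort_manifest(datasets: Iterable[MealTestDataset]) -> dict:
    """Summary of a cohort: counts, time grids and canonical units."""
    datasets = list(datasets)
    subject_ids = sorted({ds.subject.subject_id for ds in datasets})
    return {
        "n_datasets": len(datasets),
        "n_subjects": len(subject_ids),
        "subjects": subject_ids,
        "arms": sorted({ds.arm for ds in datasets}),
        "time_grids": {
            f"{ds.subject.subject_id}/{ds.arm}": list(map(float, ds.cpeptide.times))
            for ds in datasets
        },
        "units": dict(CANONICAL_UNIT),
    }
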