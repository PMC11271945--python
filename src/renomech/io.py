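"""Curve-table file I/O: validated CSV and XLSX readers/writers.

Schemas (header row mandatory, UTF-8, "." decimal):

==================== =================================================
test type            columns
==================== =================================================
tension              sample_id, time_s, eng_strain, eng_stress_MPa
relaxation           sample_id, time_s, eng_stress_MPa
confined_compression sample_id, vol_strain, pressure_MPa
==================== =================================================

Engineering strain is elongation over initial gauge length; engineering
stress is force over initial area (the axial first Piola-Kirchhoff
component).  Numeric output is written with 9 significant digits and a
deterministic column order, and values are rounded identically for CSV and
XLSX so the two formats reparse to the same numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .synthetic import SyntheticDataset

__all__ = [
    "CurveTable",
    "SCHEMAS",
    "read_curves",
    "write_curves",
    "dataset_to_curves",
    "write_dataset",
]

#: required columns and the monotone independent variable per test type
SCHEMAS: dict[str, dict] = {
    "tension": {
        "columns": ["sample_id", "time_s", "eng_strain", "eng_stress_MPa"],
        "independent": "eng_strain",
    },
    "relaxation": {
        "columns": ["sample_id", "time_s", "eng_stress_MPa"],
        "independent": "time_s",
    },
    "confined_compression": {
        "columns": ["sample_id", "vol_strain", "pressure_MPa"],
        "independent": "vol_strain",
    },
}


@dataclass
class CurveTable:
    """One validated per-sample curve with its condition metadata."""

    data: pd.DataFrame
    test_type: str
    sample_id: str
    rate: float | None = None
    metadata: dict = field(default_factory=dict)


def _round_sig(x: float, sig: int = 9) -> float:
    if x == 0.0 or not math.isfinite(x):
        return x
    return float(f"%.{sig}g" % x)


def _round_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(_round_sig)
    return out


def _validate_frame(df: pd.DataFrame, test_type: str, source: str) -> list[CurveTable]:
    if test_type not in SCHEMAS:
        raise ParseError(f"unknown test type {test_type!r}")
    schema = SCHEMAS[test_type]
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise ParseError(f"{source}: missing required column(s) {missing}")
    numeric_cols = [c for c in schema["columns"] if c != "sample_id"]
    for col in numeric_cols:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | ~np.isfinite(values)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{source}: non-numeric or non-finite value in column {col!r} at row {row}"
            )
        df[col] = values.astype(float)
    curves: list[CurveTable] = []
    for sid, group in df.groupby("sample_id", sort=True):
        group = group.reset_index(drop=True)
        x = group[schema["independent"]].to_numpy()
        steps = np.diff(x)
        if np.any(steps <= 0.0):
            row = int(np.flatnonzero(steps <= 0.0)[0]) + 1
            raise ParseError(
                f"{source}: sample {sid!r} column {schema['independent']!r} "
                f"not strictly increasing at row {row}"
            )
        rate = None
        if test_type == "tension" and group["time_s"].iloc[-1] > 0.0:
            rate = float(group["eng_strain"].iloc[-1] / group["time_s"].iloc[-1])
        curves.append(
            CurveTable(
                data=group[schema["columns"]].copy(),
                test_type=test_type,
                sample_id=str(sid),
                rate=rate,
                metadata={"source": source},
            )
        )
    return curves


def read_curves(path, test_type: str, sheet_map: dict | None = None) -> list[CurveTable]:
    """Read and validate curve tables from a CSV file, directory, or XLSX.

    A directory is scanned for ``*.csv``; an XLSX workbook is read sheet by
    sheet (``sheet_map`` may restrict/rename sheets to read, mapping sheet
    name -> label).  Multi-sample tables are split on ``sample_id``.
    """
    p = Path(path)
    if not p.exists():
        raise ParseError(f"input path {p} does not exist")
    curves: list[CurveTable] = []
    if p.is_dir():
        files = sorted(p.glob("*.csv"))
        if not files:
            raise ParseError(f"directory {p} contains no CSV files")
        for f in files:
            curves.extend(_validate_frame(pd.read_csv(f), test_type, f.name))
    elif p.suffix.lower() in (".xlsx", ".xlsm"):
        sheets = pd.read_excel(p, sheet_name=None, engine="openpyxl")
        if sheet_map is not None:
            sheets = {k: v for k, v in sheets.items() if k in sheet_map}
            if not sheets:
                raise ParseError(f"{p.name}: no sheets match the given sheet map")
        for name, df in sheets.items():
            curves.extend(_validate_frame(df, test_type, f"{p.name}:{name}"))
    else:
        curves.extend(_validate_frame(pd.read_csv(p), test_type, p.name))
    return curves


def write_curves(curves: list[CurveTable], path, format: str = "csv") -> None:
    """Write curve tables to one CSV (or XLSX workbook, one sheet per group).

    Column order follows the schema; floats carry 9 significant digits in
    both formats so CSV and XLSX round-trip to identical values.
    """
    if not curves:
        raise ParseError("no curves to write")
    test_type = curves[0].test_type
    if any(c.test_type != test_type for c in curves):
        raise ParseError("cannot mix test types in one file")
    cols = SCHEMAS[test_type]["columns"]
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        combined = pd.concat([_round_frame(c.data[cols]) for c in curves], ignore_index=True)
        combined.to_csv(p, index=False, float_format="%.9g")
    elif format == "xlsx":
        groups: dict[str, list[pd.DataFrame]] = {}
        for c in curves:
            key = c.metadata.get("condition", test_type)
            groups.setdefault(str(key), []).append(_round_frame(c.data[cols]))
        with pd.ExcelWriter(p, engine="openpyxl") as writer:
            for name in sorted(groups):
                pd.concat(groups[name], ignore_index=True).to_excel(
                    writer, sheet_name=name[:31], index=False
                )
    else:
        raise ParseError(f"unknown format {format!r}; use 'csv' or 'xlsx'")


def dataset_to_curves(dataset: SyntheticDataset, kind: str) -> list[CurveTable]:
    """Convert generated sample records of one kind into curve tables."""
    out: list[CurveTable] = []
    for rec in dataset.records:
        if rec.kind != kind:
            continue
        condition = kind if rec.rate is None else f"{kind}_{rec.rate:g}"
        out.append(
            CurveTable(
                data=rec.data.copy(),
                test_type=kind,
                sample_id=rec.sample_id,
                rate=rec.rate,
                metadata={"condition": condition, "truth": dict(rec.truth)},
            )
        )
    return out


def write_dataset(dataset: SyntheticDataset, outdir, xlsx: bool = False) -> Path:
    """Write a synthetic dataset as one CSV per sample plus a YAML manifest.

    The manifest embeds the full generating recipe (the truth record), so a
    dataset on disk is reproducible from the manifest alone.  With
    ``xlsx=True`` an additional single-workbook export with one sheet per
    condition is written next to the CSVs, mimicking a supplementary-data
    workbook.
    """
    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    kinds = sorted({r.kind for r in dataset.records})
    for kind in kinds:
        for curve in dataset_to_curves(dataset, kind):
            write_curves([curve], out / f"{curve.sample_id}.csv", format="csv")
        if xlsx:
            write_curves(
                dataset_to_curves(dataset, kind), out / f"{kind}.xlsx", format="xlsx"
            )
    manifest = {
        "recipe": dataset.recipe.to_dict(),
        "kinds": kinds,
        "files": sorted(f"{r.sample_id}.csv" for r in dataset.records),
    }
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out
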