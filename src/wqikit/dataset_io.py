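"""Reading sample tables and criteria configs; writing the three-part report.

Datasets are wide tables: one row per sample, one column per parameter
(concentrations in mg/L, turbidity in NTU, pH unitless).  A parameter
column may be paired with a ``<name>_code`` column carrying per-record
selection codes (+1 include, -1 exclude, 0 no data).  Blank or NA cells are
missing values — the engine treats them as selection code 0 automatically.

Reports have three parts mirroring the classic monitoring-report workbook:
"Original Data" (the input echoed verbatim), "Quality Values" (each
parameter's contribution per sample) and "Water Quality Index" (the total
plus its interpretation), written either as a multi-sheet .xlsx workbook or
as three CSV files.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .wqi_core import (
    MISSING,
    CriteriaSet,
    ParameterSpec,
    SampleRecord,
    WQIError,
    WQIResult,
)

__all__ = [
    "Dataset",
    "DatasetIOError",
    "read_criteria",
    "write_criteria",
    "read_dataset",
    "dataset_to_frame",
    "write_report",
    "read_report_part",
    "REPORT_PARTS",
]

logger = logging.getLogger(__name__)

REPORT_PARTS = ("Original Data", "Quality Values", "Water Quality Index")

_CODE_SUFFIX = "_code"
_META_COLUMNS = ("sample_id", "location")


class DatasetIOError(ValueError):
    """Raised on malformed input files."""


@dataclass
class Dataset:
    """A criteria set plus the sample records governed by it."""

    criteria: CriteriaSet
    records: list[SampleRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# criteria configuration (JSON)

def read_criteria(path: str | Path) -> CriteriaSet:
    """Load a criteria configuration from JSON.

    Each entry needs ``name`` and ``weight`` plus either ``limit`` or the
    pH-style pair ``band_low``/``band_high``; ``included`` defaults true.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DatasetIOError(f"{path}: not valid JSON ({exc})") from exc
    entries = payload.get("parameters") if isinstance(payload, dict) else payload
    if not isinstance(entries, list):
        raise DatasetIOError(f"{path}: expected a 'parameters' list")
    specs = []
    for entry in entries:
        kind = "band" if "band_low" in entry or "band_high" in entry else "upper_limit"
        try:
            specs.append(
                ParameterSpec(
                    name=entry["name"],
                    weight=float(entry["weight"]),
                    limit_kind=kind,
                    limit=float(entry["limit"]) if "limit" in entry else None,
                    band_low=float(entry["band_low"]) if "band_low" in entry else None,
                    band_high=float(entry["band_high"]) if "band_high" in entry else None,
                    included=bool(entry.get("included", True)),
                )
            )
        except (KeyError, TypeError, ValueError, WQIError) as exc:
            raise DatasetIOError(f"{path}: bad parameter entry {entry!r}: {exc}") from exc
    return CriteriaSet(tuple(specs))


def write_criteria(criteria: CriteriaSet, path: str | Path) -> Path:
    """Write a criteria set as a JSON configuration file."""
    path = Path(path)
    entries = []
    for p in criteria:
        entry: dict = {"name": p.name, "weight": p.weight, "included": p.included}
        if p.limit_kind == "band":
            entry["band_low"] = p.band_low
            entry["band_high"] = p.band_high
        else:
            entry["limit"] = p.limit
        entries.append(entry)
    path.write_text(json.dumps({"parameters": entries}, indent=2) + "\n")
    return path


# ---------------------------------------------------------------------------
# dataset reading

def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return pd.read_excel(path, dtype=object)
    return pd.read_csv(path, dtype=object, skipinitialspace=True)


def read_dataset(path: str | Path, criteria: CriteriaSet) -> Dataset:
    """Parse a wide-format sample table into a Dataset.

    Unknown parameter columns are an error listing the offenders; rows with
    non-numeric cells in numeric columns are logged and skipped, with the
    count recorded in ``provenance['skipped_rows']``.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetIOError(f"{path}: no such file")
    frame = _read_table(path)
    frame.columns = [str(c).strip() for c in frame.columns]

    known = set(criteria.names)
    unknown = [
        c
        for c in frame.columns
        if c not in known
        and c not in _META_COLUMNS
        and not (c.endswith(_CODE_SUFFIX) and c[: -len(_CODE_SUFFIX)] in known)
    ]
    if unknown:
        raise DatasetIOError(
            f"{path}: unknown parameter columns {unknown}; declare them in the "
            "criteria configuration first"
        )

    param_cols = [c for c in frame.columns if c in known]
    code_cols = [c for c in frame.columns if c.endswith(_CODE_SUFFIX)]

    records: list[SampleRecord] = []
    parse_log: list[str] = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        sample_id = str(row["sample_id"]) if "sample_id" in frame.columns else f"row{pos + 1}"
        location = None
        if "location" in frame.columns and not pd.isna(row["location"]):
            location = str(row["location"])
        values: dict[str, float] = {}
        overrides: dict[str, int] = {}
        bad_cell = None
        for col in param_cols:
            cell = row[col]
            if pd.isna(cell) or (isinstance(cell, str) and not cell.strip()):
                values[col] = MISSING
                continue
            try:
                values[col] = float(cell)
            except (TypeError, ValueError):
                bad_cell = f"{col}={cell!r}"
                break
        if bad_cell is None:
            for col in code_cols:
                cell = row[col]
                if pd.isna(cell) or (isinstance(cell, str) and not cell.strip()):
                    continue
                name = col[: -len(_CODE_SUFFIX)]
                try:
                    code = int(float(cell))
                    if code not in (-1, 0, 1):
                        raise ValueError(code)
                except (TypeError, ValueError):
                    bad_cell = f"{col}={cell!r} (codes are -1, 0 or 1)"
                    break
                overrides[name] = code
        if bad_cell is not None:
            msg = f"row {pos + 1} ({sample_id}): unparseable cell {bad_cell}; row skipped"
            parse_log.append(msg)
            logger.warning("%s: %s", path, msg)
            continue
        records.append(
            SampleRecord(sample_id=sample_id, values=values, overrides=overrides, location=location)
        )

    return Dataset(
        criteria=criteria,
        records=records,
        provenance={
            "source": str(path),
            "parse_log": parse_log,
            "skipped_rows": len(parse_log),
        },
    )


def dataset_to_frame(dataset: Dataset) -> pd.DataFrame:
    """Wide-format view of a dataset: one row per sample, NaN = missing.

    Selection codes are included as ``<name>_code`` columns only where some
    record carries an override.
    """
    names = list(dataset.criteria.names)
    rows = []
    any_code = {n: False for n in names}
    for rec in dataset.records:
        row: dict = {"sample_id": rec.sample_id}
        if rec.location is not None:
            row["location"] = rec.location
        for n in names:
            v = rec.values.get(n, MISSING)
            row[n] = float(v) if v is not None else MISSING
            if n in rec.overrides:
                row[f"{n}{_CODE_SUFFIX}"] = rec.overrides[n]
                any_code[n] = True
        rows.append(row)
    frame = pd.DataFrame(rows)
    ordered = ["sample_id"]
    if "location" in frame.columns:
        ordered.append("location")
    for n in names:
        if n in frame.columns:
            ordered.append(n)
        if any_code[n]:
            ordered.append(f"{n}{_CODE_SUFFIX}")
    return frame.reindex(columns=ordered)


# ---------------------------------------------------------------------------
# report writing

def _quality_frame(
    dataset: Dataset, results: Sequence[WQIResult], digits: int | None
) -> pd.DataFrame:
    names = [n for n in dataset.criteria.names]
    rows = []
    for res in results:
        row: dict = {"sample_id": res.sample_id}
        for n in names:
            row[n] = res.quality_values.get(n, math.nan)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["sample_id"] + names)
    if digits is not None:
        frame[names] = frame[names].round(digits)
    return frame


def _index_frame(results: Sequence[WQIResult], digits: int | None) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "WQI": [r.wqi for r in results],
            "interpretation": [r.class_label for r in results],
        }
    )
    if digits is not None:
        frame["WQI"] = frame["WQI"].round(digits)
    return frame


def _part_paths(path: Path) -> dict[str, Path]:
    stem = path.with_suffix("")
    return {
        "Original Data": Path(f"{stem}_original_data.csv"),
        "Quality Values": Path(f"{stem}_quality_values.csv"),
        "Water Quality Index": Path(f"{stem}_water_quality_index.csv"),
    }


def write_report(
    dataset: Dataset,
    results: Sequence[WQIResult],
    path: str | Path,
    *,
    fmt: str | None = None,
    digits: int | None = None,
) -> list[Path]:
    """Emit the three-part report; returns the paths written.

    ``fmt`` is ``"xlsx"`` (one workbook, three sheets) or ``"csv"`` (three
    files suffixed ``_original_data`` / ``_quality_values`` /
    ``_water_quality_index``); inferred from the extension when omitted.
    The Original Data part is always written at full precision so a
    read-back reproduces the input; ``digits`` rounds only the derived
    parts for display.
    """
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() == ".xlsx" else "csv"
    if fmt not in ("csv", "xlsx"):
        raise DatasetIOError(f"unknown report format {fmt!r}; use 'csv' or 'xlsx'")
    if len(results) != len(dataset.records):
        raise DatasetIOError(
            f"results ({len(results)}) and records ({len(dataset.records)}) "
            "are not aligned 1:1"
        )
    for rec, res in zip(dataset.records, results):
        if rec.sample_id != res.sample_id:
            raise DatasetIOError(
                f"result order mismatch: record {rec.sample_id!r} vs "
                f"result {res.sample_id!r}"
            )

    frames = {
        "Original Data": dataset_to_frame(dataset),
        "Quality Values": _quality_frame(dataset, results, digits),
        "Water Quality Index": _index_frame(results, digits),
    }

    if fmt == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for sheet, frame in frames.items():
                frame.to_excel(writer, sheet_name=sheet, index=False)
        return [path]

    paths = _part_paths(path)
    for sheet, frame in frames.items():
        frame.to_csv(paths[sheet], index=False)
    return list(paths.values())


def read_report_part(path: str | Path, part: str, *, fmt: str | None = None) -> pd.DataFrame:
    """Read one part of a previously written report back into a DataFrame."""
    if part not in REPORT_PARTS:
        raise DatasetIOError(f"unknown report part {part!r}; one of {REPORT_PARTS}")
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() == ".xlsx" else "csv"
    if fmt == "xlsx":
        return pd.read_excel(path, sheet_name=part)
    return pd.read_csv(_part_paths(path)[part])
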