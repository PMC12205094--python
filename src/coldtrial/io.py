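"""CSV schema readers/writers, config parsing and the JSON report."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import TrialDesign, ValidationError
from .spatial import PHENOTYPE_FLAGS, CellMap
from .survival import (
    BOR_CATEGORIES,
    GMIRecord,
    MedianEstimate,
    ResponseRecord,
    SurvivalRecord,
)
from .synth import cell_maps_from_frames

logger = logging.getLogger("coldtrial")

PATIENT_COLUMNS = [
    "patient_id",
    "evaluable_efficacy",
    "bor",
    "response_onset_months",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
    "prior_pfs_months",
]

CELL_COLUMNS = ["sample_id", "patient_id", "timepoint", "x_um", "y_um"]
SAMPLE_COLUMNS = ["sample_id", "patient_id", "timepoint", "area_mm2"]


class SchemaError(ValidationError):
    """A required column is missing or mistyped."""


class RowError(ValidationError):
    """One or more rows violate the schema; carries line numbers."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


def read_patient_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the patient-level CSV.

    Row-level problems are collected across the whole file and reported
    together with 1-based data line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"patient table {path} lacks required columns: {missing}")
    problems: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["bor"] not in BOR_CATEGORIES and not pd.isna(row["bor"]):
            problems.append(f"line {line}: bor {row['bor']!r} outside {BOR_CATEGORIES}")
        for col in ("pfs_months", "os_months"):
            v = row[col]
            if not pd.isna(v) and float(v) < 0:
                problems.append(f"line {line}: negative {col} ({v})")
        if not pd.isna(row["prior_pfs_months"]) and float(row["prior_pfs_months"]) <= 0:
            problems.append(f"line {line}: prior_pfs_months must be > 0")
    if problems:
        raise RowError(problems)
    return df


def patients_to_survival(
    df: pd.DataFrame, endpoint: str = "PFS", time_unit_scale: float = 1.0
) -> list[SurvivalRecord]:
    """Extract survival records for one endpoint; rows with a missing
    time are skipped with a warning."""
    col_t, col_e = (
        ("pfs_months", "pfs_event") if endpoint == "PFS" else ("os_months", "os_event")
    )
    out = []
    for _, row in df.iterrows():
        if pd.isna(row[col_t]):
            logger.warning("patient %s lacks %s time; skipped", row["patient_id"], endpoint)
            continue
        out.append(
            SurvivalRecord(
                patient_id=str(row["patient_id"]),
                time=float(row[col_t]) * time_unit_scale,
                event=bool(int(row[col_e])),
                endpoint=endpoint,
            )
        )
    return out


def patients_to_response(df: pd.DataFrame) -> list[ResponseRecord]:
    out = []
    for _, row in df.iterrows():
        if not int(row["evaluable_efficacy"]):
            continue
        bor = "NE" if pd.isna(row["bor"]) else str(row["bor"])
        onset = (
            None
            if pd.isna(row["response_onset_months"])
            else float(row["response_onset_months"])
        )
        out.append(
            ResponseRecord(
                patient_id=str(row["patient_id"]),
                best_overall_response=bor,
                progression_or_censor_time=float(row["pfs_months"]),
                progressed=bool(int(row["pfs_event"])),
                response_onset_time=onset,
            )
        )
    return out


def patients_to_gmi(df: pd.DataFrame) -> list[GMIRecord]:
    out = []
    for _, row in df.iterrows():
        if pd.isna(row["prior_pfs_months"]) or pd.isna(row["pfs_months"]):
            continue
        out.append(
            GMIRecord(
                patient_id=str(row["patient_id"]),
                pfs_current=float(row["pfs_months"]),
                pfs_prior=float(row["prior_pfs_months"]),
                pfs_current_censored=not bool(int(row["pfs_event"])),
            )
        )
    return out


def read_cell_tables(
    cells_path: str | Path, samples_path: str | Path
) -> list[CellMap]:
    cells = pd.read_csv(cells_path)
    samples = pd.read_csv(samples_path)
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cells table lacks required columns: {missing}")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise SchemaError(f"samples table lacks required columns: {missing}")
    return cell_maps_from_frames(cells, samples)


def load_config(path: str | Path) -> dict[str, Any]:
    """YAML (or JSON, a YAML subset) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def design_from_config(cfg: dict[str, Any]) -> TrialDesign:
    return TrialDesign(**cfg.get("design", {}))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, MedianEstimate):
        return {
            "median": obj.median,
            "ci_low": obj.ci_low,
            "ci_high": obj.ci_high,
            "not_reached": obj.not_reached,
        }
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(
    results: dict[str, Any],
    path: str | Path,
    seed: Optional[int] = None,
    config: Optional[dict[str, Any]] = None,
) -> dict[str, Any]:
    """Write the combined JSON report.

    Every report embeds the tool version, the seed and the config echo
    needed to regenerate it.  "Not reached" medians serialize as null
    plus a ``not_reached`` flag.
    """
    payload = {
        "tool": "coldtrial",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config) if config else None,
        "results": _jsonable(results),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload
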