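"""File formats: session CSV, cohort CSV, reports, and model files.

All CSVs are comma-separated UTF-8 with a header row and "." decimals.
Reports serialize to JSON (full float precision) or flat CSV; prediction
models round-trip through a plain-text ``key = value`` file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import ValidationError
from .estimation import PhysioTimeSeries, SessionReport
from .prediction import PredictionModel

__all__ = [
    "read_session_csv",
    "write_session_csv",
    "read_cohort_csv",
    "report_to_dict",
    "write_report",
    "read_report",
    "write_model",
    "read_model",
]

SESSION_COLUMNS = ["time_s", "hr_bpm", "vo2_mlkgmin", "phase"]
IPAQ_COLUMNS = [
    "participant_id",
    "vigorous_days", "vigorous_min",
    "moderate_days", "moderate_min",
    "walking_days", "walking_min",
]


def read_session_csv(path: str | Path) -> PhysioTimeSeries:
    """Parse and validate a session time-series CSV.

    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers. Blank VO2 cells are accepted and validated downstream (recovery
    only).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[pd.to_numeric(df["time_s"], errors="coerce").isna()
                   | pd.to_numeric(df["hr_bpm"], errors="coerce").isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]
        raise ValidationError(f"{path}: non-numeric time/hr at line(s) {lines}")
    df["time_s"] = df["time_s"].astype(float)
    df["hr_bpm"] = df["hr_bpm"].astype(float)
    df["vo2_mlkgmin"] = pd.to_numeric(df["vo2_mlkgmin"], errors="coerce")
    return PhysioTimeSeries(df[SESSION_COLUMNS])


def write_session_csv(ts: PhysioTimeSeries, path: str | Path) -> None:
    ts.df.to_csv(path, index=False)


def read_cohort_csv(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a cohort table, checking for a required column set."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path)
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def _jsonable(value: Any) -> Any:
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, tuple):
        return [_jsonable(v) for v in value]
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(value).items()}
    return value


def report_to_dict(report: Any) -> dict:
    """Flatten any result dataclass into JSON-serializable primitives."""
    if not dataclasses.is_dataclass(report):
        raise ValidationError(f"not a report dataclass: {type(report).__name__}")
    return _jsonable(report)


def write_report(report: Any, path: str | Path, fmt: str = "json") -> None:
    """Serialize a report dataclass to JSON (default) or a flat one-row CSV."""
    data = report_to_dict(report)
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    elif fmt == "csv":
        flat = {}
        for key, val in data.items():
            if isinstance(val, list):
                for i, v in enumerate(val):
                    flat[f"{key}_{i}"] = v
            elif isinstance(val, dict):
                for k, v in val.items():
                    flat[f"{key}.{k}"] = v
            else:
                flat[key] = val
        pd.DataFrame([flat]).to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown report format {fmt!r}")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_model(model: PredictionModel, path: str | Path) -> None:
    """Plain-text key-value model file, full float precision (repr)."""
    lines = [f"# r2 = {model.r2!r}", f"# see = {model.see!r}", f"# n = {model.n!r}"]
    lines.append(f"intercept = {model.coefficients['intercept']!r}")
    for name in model.retained:
        lines.append(f"{name} = {model.coefficients[name]!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> PredictionModel:
    """Round-trip counterpart of :func:`write_model`."""
    coefficients: dict[str, float] = {}
    meta: dict[str, float | None] = {"r2": None, "see": None, "n": None}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                if key in meta:
                    val = val.strip()
                    meta[key] = None if val == "None" else float(val)
            continue
        key, sep, val = line.partition("=")
        if not sep:
            raise ValidationError(f"malformed model line: {raw!r}")
        coefficients[key.strip()] = float(val.strip())
    if "intercept" not in coefficients:
        raise ValidationError("model file lacks an intercept")
    retained = tuple(k for k in coefficients if k != "intercept")
    n = meta["n"]
    return PredictionModel(
        coefficients=coefficients,
        retained=retained,
        r2=meta["r2"],
        see=meta["see"],
        n=int(n) if n is not None else None,
    )
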