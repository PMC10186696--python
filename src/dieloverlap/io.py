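"""CSV and JSON input/output with validated, canonical dialects.

All CSVs are UTF-8 with a header row, ISO 8601 timestamps and period
decimals.  Writers emit a canonical formatting so write -> read -> write is
byte-identical.  Schemas:

* observations: ``site, role, timestamp``        (role: prey|predator|potential)
* tb:           ``individual_id, temp_c, hour``
* to:           ``logger_id, microenv, timestamp, temp_c``
* vipers:       ``population, sex, svl_mm, injured``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "read_observations", "write_observations",
    "read_tb", "write_tb",
    "read_to", "write_to",
    "read_vipers", "write_vipers",
    "write_json", "write_density_csv", "write_replicates_csv",
]

ROLES = ("prey", "predator", "potential")
SEXES = ("male", "female", "unknown")


def _read(path, columns: tuple[str, ...], dtypes: dict | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"{path}: cannot read CSV ({exc})") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise InputError(f"{path}: no records (header only)")
    return df[list(columns)]


def _to_float(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = np.where(~np.isfinite(vals.to_numpy(dtype=float)))[0]
    if bad.size:
        raise InputError(
            f"{path}: row {bad[0] + 2}, column {col!r}: "
            f"not a finite number ({df[col].iloc[bad[0]]!r})"
        )
    return vals.to_numpy(dtype=float)


def _to_timestamp(df: pd.DataFrame, col: str, path) -> pd.Series:
    ts = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
    bad = np.where(ts.isna().to_numpy())[0]
    if bad.size:
        raise InputError(
            f"{path}: row {bad[0] + 2}, column {col!r}: "
            f"unparseable ISO 8601 timestamp ({df[col].iloc[bad[0]]!r})"
        )
    return ts


def _check_levels(df: pd.DataFrame, col: str, levels, path):
    bad = np.where(~df[col].isin(levels).to_numpy())[0]
    if bad.size:
        raise InputError(
            f"{path}: row {bad[0] + 2}, column {col!r}: "
            f"{df[col].iloc[bad[0]]!r} not in {list(levels)}"
        )


def read_observations(path) -> pd.DataFrame:
    """Time-stamped observation records (site, role, timestamp)."""
    df = _read(path, ("site", "role", "timestamp"))
    _check_levels(df, "role", ROLES, path)
    out = pd.DataFrame({
        "site": df["site"],
        "role": df["role"],
        "timestamp": _to_timestamp(df, "timestamp", path),
    })
    return out


def write_observations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out[["site", "role", "timestamp"]].to_csv(path, index=False, lineterminator="\n")


def read_tb(path) -> pd.DataFrame:
    """Gradient-selected body temperatures (individual_id, temp_c, hour)."""
    df = _read(path, ("individual_id", "temp_c", "hour"))
    return pd.DataFrame({
        "individual_id": df["individual_id"],
        "temp_c": _to_float(df, "temp_c", path),
        "hour": _to_float(df, "hour", path),
    })


def write_tb(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["temp_c"] = out["temp_c"].map(lambda v: f"{v:.3f}")
    out["hour"] = out["hour"].map(lambda v: f"{v:.3f}")
    out[["individual_id", "temp_c", "hour"]].to_csv(
        path, index=False, lineterminator="\n"
    )


def read_to(path) -> pd.DataFrame:
    """Operative-temperature logger records."""
    df = _read(path, ("logger_id", "microenv", "timestamp", "temp_c"))
    return pd.DataFrame({
        "logger_id": df["logger_id"],
        "microenv": df["microenv"],
        "timestamp": _to_timestamp(df, "timestamp", path),
        "temp_c": _to_float(df, "temp_c", path),
    })


def write_to(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out["temp_c"] = out["temp_c"].map(lambda v: f"{v:.3f}")
    out[["logger_id", "microenv", "timestamp", "temp_c"]].to_csv(
        path, index=False, lineterminator="\n"
    )


def read_vipers(path) -> pd.DataFrame:
    """Capture records (population, sex, svl_mm, injured)."""
    df = _read(path, ("population", "sex", "svl_mm", "injured"))
    _check_levels(df, "sex", SEXES, path)
    _check_levels(df, "injured", ("True", "False", "true", "false", "0", "1"), path)
    svl = _to_float(df, "svl_mm", path)
    bad = np.where(svl <= 0)[0]
    if bad.size:
        raise InputError(
            f"{path}: row {bad[0] + 2}, column 'svl_mm': must be positive"
        )
    return pd.DataFrame({
        "population": df["population"],
        "sex": df["sex"],
        "svl_mm": svl,
        "injured": df["injured"].isin(("True", "true", "1")),
    })


def write_vipers(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["svl_mm"] = out["svl_mm"].map(lambda v: f"{v:.1f}")
    out["injured"] = out["injured"].map(lambda v: "True" if v else "False")
    out[["population", "sex", "svl_mm", "injured"]].to_csv(
        path, index=False, lineterminator="\n"
    )


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, fixed float repr, newline at EOF."""
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, allow_nan=False) + "\n",
        encoding="utf-8",
    )


def write_density_csv(curves: dict, path) -> None:
    """Densities on a shared grid: one 'angle' column plus one per curve."""
    first = next(iter(curves.values()))
    data = {"angle": [f"{a:.8f}" for a in first.grid]}
    for name, curve in curves.items():
        data[name] = [f"{v:.8e}" for v in curve.values]
    pd.DataFrame(data).to_csv(path, index=False, lineterminator="\n")


def write_replicates_csv(results: dict, path) -> None:
    """Bootstrap replicate Delta values, one column per comparison."""
    data = {name: [f"{v:.8f}" for v in r.replicates] for name, r in results.items()}
    pd.DataFrame(data).to_csv(path, index=False, lineterminator="\n")
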