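"""CSV/XLSX round-tripping, schema checks, configuration and provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, SchemaError

#: Required columns of a tidy observation table; ``plant`` is optional
#: (used to group leaves into plant samples when present).
OBS_COLUMNS = (
    "season",
    "cultivar",
    "n_level",
    "density",
    "ndpd",
    "stage",
    "rank",
    "total_leaves",
    "biomass_g",
)

_NUMERIC = {"ndpd": float, "rank": int, "total_leaves": int, "biomass_g": float}


def validate_observations(df: pd.DataFrame, require_stage: bool = True) -> pd.DataFrame:
    """Check an observation table against the schema; returns a typed copy.

    Raises :class:`SchemaError` naming the offending column.
    """
    if df.empty:
        raise SchemaError("observation table is empty")
    required = [c for c in OBS_COLUMNS if require_stage or c != "stage"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    df = df.copy()
    for col, typ in _NUMERIC.items():
        if col not in df.columns:
            continue
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"column {col!r} is not numeric: {exc}") from None
    if ((df["ndpd"] < 0) | (df["ndpd"] > 1)).any():
        raise SchemaError("column 'ndpd' has values outside [0, 1]")
    if (df["rank"] < 1).any():
        raise SchemaError("column 'rank' has values below 1")
    if (df["rank"] > df["total_leaves"]).any():
        raise SchemaError("column 'rank' exceeds 'total_leaves'")
    if (df["biomass_g"] < 0).any():
        raise SchemaError("column 'biomass_g' has negative values")
    return df


def read_observations(path, require_stage: bool = True) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"observation file {path} is empty") from None
    return validate_observations(df, require_stage=require_stage)


def write_observations(df: pd.DataFrame, path) -> None:
    """Write observations at full precision (lossless CSV round trip)."""
    df.to_csv(path, index=False)


def write_report(df: pd.DataFrame, path, sigfigs: int = 6) -> None:
    """Write a report table with numeric columns at ``sigfigs`` significant digits."""
    df.to_csv(path, index=False, float_format=f"%.{sigfigs}g")


def read_supplementary_xlsx(
    path,
    column_map: Mapping[str, str],
    sheet_name: int | str = 0,
) -> pd.DataFrame:
    """Best-effort ingestion of a supplementary XLSX observation table.

    ``column_map`` maps source headers to schema column names; columns
    not mentioned are dropped.  Requires ``openpyxl``.
    """
    df = pd.read_excel(path, sheet_name=sheet_name)
    missing = set(column_map) - set(df.columns)
    if missing:
        raise SchemaError(f"XLSX file lacks mapped columns: {sorted(missing)}")
    df = df[list(column_map)].rename(columns=dict(column_map))
    return validate_observations(df, require_stage="stage" in df.columns)


# ---------------------------------------------------------------------------
# configuration and provenance
# ---------------------------------------------------------------------------


def load_config(path, allowed_keys: Iterable[str]) -> dict:
    """Load a YAML config mapping, rejecting unknown keys."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    unknown = set(data) - set(allowed_keys)
    if unknown:
        raise ConfigError(
            f"unknown config keys {sorted(unknown)}; allowed: {sorted(allowed_keys)}"
        )
    return data


def config_digest(config: Mapping) -> str:
    """Stable SHA-256 digest of a configuration mapping."""

    def default(o):
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    canon = json.dumps(config, sort_keys=True, default=default)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_provenance(out_path, command: str, seed: int | None, config: Mapping) -> Path:
    """Write a JSON provenance sidecar next to an output file."""
    out_path = Path(out_path)
    sidecar = out_path.with_suffix(out_path.suffix + ".prov.json")
    payload = {
        "package": "leafpart",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config_sha256": config_digest(config),
        "config": json.loads(json.dumps(config, default=str)),
    }
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return sidecar
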