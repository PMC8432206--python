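"""Cohort CSV and parameter JSON/YAML readers and writers.

Cohort files are plain CSV with a header, one row per pregnancy.  Mandatory
columns: ``ga_delivery``, ``z_bw``, ``pe``; marker columns are named
``mom_<marker>``; any additional columns (covariates or otherwise) are
preserved on a round trip.  Numeric fields survive a write/read cycle to 12
significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .folded_plane import FoldedPlaneParams
from .prior import PriorParams

__all__ = [
    "MANDATORY_COLUMNS",
    "read_cohort",
    "write_cohort",
    "read_folded_plane",
    "write_folded_plane",
    "read_prior",
    "write_prior",
    "read_run_config",
]

MANDATORY_COLUMNS = ("ga_delivery", "z_bw", "pe")
_NUMERIC = ("ga_delivery", "z_bw", "ga_measurement")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating schema and numeric outcome fields."""
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing mandatory columns: {missing}")
    for col in _NUMERIC:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric {col!r} values at rows {list(bad[:5])} of {path}"
            )
        df[col] = coerced
    return df


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write a cohort CSV preserving 12 significant digits of numeric fields."""
    missing = [c for c in MANDATORY_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"cohort frame is missing mandatory columns: {missing}")
    records.to_csv(path, index=False, float_format="%.12g")


def write_folded_plane(params: FoldedPlaneParams, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def read_folded_plane(path) -> FoldedPlaneParams:
    return FoldedPlaneParams.from_dict(json.loads(Path(path).read_text()))


def write_prior(prior: PriorParams, path) -> None:
    path = Path(path)
    d = prior.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d))
    else:
        path.write_text(json.dumps(d, indent=2) + "\n")


def read_prior(path) -> PriorParams:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return PriorParams.from_dict(d)


def read_run_config(path) -> dict:
    """Read a pipeline run configuration (YAML or JSON) as a plain dict."""
    path = Path(path)
    text = path.read_text()
    return yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
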