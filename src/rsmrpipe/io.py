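"""Delimited-text readers/writers for claims bundles and artifacts.

Interchange dialect: comma-separated UTF-8 with a header row; code lists
within a cell are semicolon-joined. A manifest JSON records the generating
config and seed next to the three bundle tables. Schemas are versioned via
the manifest's ``schema`` field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (
    BENEFICIARY_COLUMNS,
    DISPOSITIONS,
    ENCOUNTER_COLUMNS,
    INPATIENT_COLUMNS,
    ClaimsBundle,
    SimulationConfig,
)

__all__ = ["write_claims_bundle", "read_claims_bundle", "config_hash"]

SCHEMA_VERSION = 1

_FILES = {
    "beneficiaries": ("beneficiaries.csv", BENEFICIARY_COLUMNS),
    "inpatient": ("inpatient.csv", INPATIENT_COLUMNS),
    "encounters": ("encounters.csv", ENCOUNTER_COLUMNS),
}

_INT_COLUMNS = {
    "beneficiaries": ["birth_day", "ffs_start", "ffs_end"],
    "inpatient": ["admission_day", "discharge_day"],
    "encounters": ["day"],
}
_OPTIONAL_FLOAT = {"beneficiaries": ["mc_start", "mc_end", "death_day"]}


class SchemaError(ValueError):
    """A bundle file violated its schema; the message names file/line/column."""


def config_hash(config) -> str:
    if dataclasses.is_dataclass(config):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_claims_bundle(
    bundle: ClaimsBundle, directory, *, config: SimulationConfig | None = None
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle.validate()
    for attr, (fname, cols) in _FILES.items():
        getattr(bundle, attr)[cols].to_csv(directory / fname, index=False)
    manifest = {
        "schema": SCHEMA_VERSION,
        "files": {a: f for a, (f, _) in _FILES.items()},
        "config": dataclasses.asdict(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
        "config_hash": config_hash(config) if config is not None else None,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
        fh.write("\n")
    return directory


def _check_int(df: pd.DataFrame, table: str, fname: str, col: str) -> pd.Series:
    parsed = pd.to_numeric(df[col], errors="coerce")
    bad = parsed.isna() | (parsed != np.floor(parsed.fillna(0)))
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise SchemaError(
            f"{fname}, line {line}, column {col!r}: "
            f"unparseable integer value {df[col].iloc[bad.idxmax()]!r}"
        )
    return parsed.astype(np.int64)


def read_claims_bundle(directory) -> ClaimsBundle:
    """Read and validate a bundle directory written by
    :func:`write_claims_bundle`. Schema violations raise
    :class:`SchemaError` naming the file, line and column."""
    directory = Path(directory)
    tables = {}
    for attr, (fname, cols) in _FILES.items():
        path = directory / fname
        if not path.exists():
            raise SchemaError(f"missing bundle file: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = set(cols) - set(df.columns)
        if missing:
            raise SchemaError(f"{fname}: missing columns {sorted(missing)}")
        df = df[cols].copy()
        for col in _INT_COLUMNS.get(attr, []):
            df[col] = _check_int(df, attr, fname, col)
        for col in _OPTIONAL_FLOAT.get(attr, []):
            raw = df[col].replace("", np.nan)
            parsed = pd.to_numeric(raw, errors="coerce")
            bad = parsed.isna() & raw.notna()
            if bad.any():
                line = int(bad.idxmax()) + 2
                raise SchemaError(
                    f"{fname}, line {line}, column {col!r}: "
                    f"unparseable value {raw.iloc[bad.idxmax()]!r}"
                )
            df[col] = parsed
        tables[attr] = df

    inpat = tables["inpatient"]
    bad = ~inpat["disposition"].isin(DISPOSITIONS)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise SchemaError(
            f"inpatient.csv, line {line}, column 'disposition': "
            f"unknown value {inpat['disposition'].iloc[bad.idxmax()]!r}"
        )
    bundle = ClaimsBundle(tables["beneficiaries"], inpat, tables["encounters"])
    bundle.validate()
    return bundle
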