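"""On-disk representation of an EMR store: one CSV per module + JSON manifest.

CSV uses RFC-4180 quoting, ISO-8601 dates and ``true``/``false`` boolean
literals; the manifest records the covered period, per-module row counts and
a schema version.  The representation is diffable and language-neutral, and
write→load is the identity — soft-deleted entries are never dropped.
"""

from __future__ import annotations

import csv
import json
from datetime import date
from pathlib import Path

import pandas as pd

import numpy as np

from .model import (
    EMRDatabase,
    MODULE_SCHEMAS,
    _BOOL_COLUMNS,
    _DATE_COLUMNS,
    _FLOAT_COLUMNS,
    coerce_module,
    empty_module,
)

SCHEMA_VERSION = 1
MANIFEST_NAME = "manifest.json"


class DatabaseLoadError(Exception):
    """Raised when an on-disk store is missing a module or is malformed."""


def write_database(db: EMRDatabase, path: str | Path) -> list[Path]:
    """Serialise *db* under directory *path*; returns the files written."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for module, frame in db.modules.items():
        out = frame.copy()
        for c in out.columns:
            if c in _DATE_COLUMNS:
                out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
            elif c in _BOOL_COLUMNS:
                out[c] = out[c].map({True: "true", False: "false"})
        fp = path / f"{module}.csv"
        out.to_csv(fp, index=False, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        written.append(fp)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "period": [db.period[0].isoformat(), db.period[1].isoformat()],
        "counts": db.n_entries(),
    }
    mp = path / MANIFEST_NAME
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mp)
    return written


def _parse_bool(col: pd.Series, module: str) -> pd.Series:
    mapped = col.map({"true": True, "false": False})
    if mapped.isna().any():
        bad = col[mapped.isna()].iloc[0]
        raise DatabaseLoadError(f"module {module!r}: invalid boolean literal {bad!r}")
    return mapped


def load_database(path: str | Path) -> EMRDatabase:
    """Load a store written by :func:`write_database`.

    Raises :class:`DatabaseLoadError` naming the module when a module file is
    missing, and a parse error with a row reference on malformed dates.
    """
    path = Path(path)
    mp = path / MANIFEST_NAME
    if not mp.exists():
        raise DatabaseLoadError(f"missing manifest {MANIFEST_NAME} in {path}")
    manifest = json.loads(mp.read_text())
    period = (date.fromisoformat(manifest["period"][0]),
              date.fromisoformat(manifest["period"][1]))
    modules: dict[str, pd.DataFrame] = {}
    for module, cols in MODULE_SCHEMAS.items():
        fp = path / f"{module}.csv"
        if not fp.exists():
            raise DatabaseLoadError(f"missing module file for {module!r}: {fp.name}")
        raw = pd.read_csv(fp, dtype=str, keep_default_na=False)
        if len(raw) == 0:
            modules[module] = empty_module(module)
            continue
        for c in cols:
            if c not in raw.columns:
                raise DatabaseLoadError(f"module {module!r}: missing column {c!r}")
            if c in _DATE_COLUMNS:
                parsed = pd.to_datetime(raw[c], format="%Y-%m-%d", errors="coerce")
                if parsed.isna().any():
                    row = int(parsed.index[parsed.isna()][0])
                    raise DatabaseLoadError(
                        f"module {module!r}, row {row}: malformed date {raw[c].iloc[row]!r}")
                raw[c] = parsed
            elif c in _BOOL_COLUMNS:
                raw[c] = _parse_bool(raw[c], module)
            elif c in _FLOAT_COLUMNS:
                raw[c] = raw[c].replace("", np.nan)
        modules[module] = coerce_module(module, raw)
    return EMRDatabase(period=period, modules=modules)
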