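"""Step 2 of the extraction: materialise the nine-table register.

For the patients of a caseset, the extractor copies the selected fields of
every module into a register of nine tables (eight structured, one
narrative), each row date-sorted and tagged with its PIN, a stable item
identifier and a deleted-provenance mark.  With ``include_deleted=True`` the
extractor behaves like a tool reading the physical store: soft-deleted
entries are emitted too, which is exactly what produces extraction-only
items in the downstream congruity audit.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .casefind import CaseSet
from .model import (
    EMRDatabase,
    MODULE_SCHEMAS,
    REGISTER_TABLE_OF_MODULE,
    REGISTER_TABLES,
    DELETABLE_MODULES,
    item_ids,
)

_MODULE_OF_TABLE = {t: m for m, t in REGISTER_TABLE_OF_MODULE.items()}


class StaleCaseSetError(Exception):
    """The caseset was derived from a different database."""


class ExtractionSpecError(ValueError):
    """Malformed extraction specification."""


@dataclass
class ExtractionSpec:
    """What to extract per table.

    ``tables`` maps register table names to the field list to copy (``None``
    = all schema fields).  ``subheadings`` restricts the narrative table;
    ``None`` means every subheading present in the store, an explicit empty
    selection is rejected.  ``date_range`` optionally restricts dated rows.
    """

    tables: dict[str, list[str] | None] = field(
        default_factory=lambda: {t: None for t in REGISTER_TABLES})
    subheadings: list[str] | None = None
    include_deleted: bool = False
    date_range: tuple | None = None

    def __post_init__(self) -> None:
        unknown = set(self.tables) - set(REGISTER_TABLES)
        if unknown:
            raise ExtractionSpecError(f"unknown register table(s): {sorted(unknown)}")
        if "Terminology" in self.tables and self.subheadings is not None \
                and len(self.subheadings) == 0:
            raise ExtractionSpecError(
                "Terminology selected but the subheading selection is empty")
        for table, fields_ in self.tables.items():
            if fields_ is None:
                continue
            schema = MODULE_SCHEMAS[_MODULE_OF_TABLE[table]]
            bad = set(fields_) - set(schema)
            if bad:
                raise ExtractionSpecError(
                    f"table {table!r}: unknown field(s) {sorted(bad)}")


@dataclass
class Register:
    """The nine-table extraction output.

    Every row carries ``pin``, ``item_id`` (stable source join key) and — for
    deletable modules — the ``deleted`` provenance mark.
    """

    tables: dict[str, pd.DataFrame]
    caseset_pins: frozenset[str]
    db_fingerprint: str

    def n_items(self, pins: set[str] | None = None) -> int:
        total = 0
        for f in self.tables.values():
            total += len(f) if pins is None else int(f["pin"].isin(pins).sum())
        return total

    def items_per_table(self, pins: set[str] | None = None) -> dict[str, int]:
        return {
            t: (len(f) if pins is None else int(f["pin"].isin(pins).sum()))
            for t, f in self.tables.items()
        }


def _empty_register_table(table: str, fields_: list[str] | None) -> pd.DataFrame:
    module = _MODULE_OF_TABLE[table]
    schema = fields_ if fields_ is not None else MODULE_SCHEMAS[module]
    cols = ["item_id"] + list(schema)
    if "pin" not in cols:
        cols.insert(1, "pin")
    if module in DELETABLE_MODULES and "deleted" not in cols:
        cols.append("deleted")
    return pd.DataFrame({c: pd.Series([], dtype=object) for c in cols})


def extract_register(db: EMRDatabase, caseset: CaseSet,
                     spec: ExtractionSpec | None = None) -> Register:
    """Materialise the register for the caseset's patients.

    Rows are filtered to caseset PINs, optionally restricted by date range,
    stably sorted by date (ties keep source order), and tagged with item
    identifiers computed on the *source* module so that every register row
    joins back to its source entry.
    """
    spec = spec or ExtractionSpec()
    if caseset.db_fingerprint != db.fingerprint():
        raise StaleCaseSetError(
            "caseset fingerprint does not match the database it is applied to")
    pins = caseset.pins
    tables: dict[str, pd.DataFrame] = {}
    for table in REGISTER_TABLES:
        if table not in spec.tables:
            tables[table] = _empty_register_table(table, None)
            continue
        module = _MODULE_OF_TABLE[table]
        src = db.modules[module]
        frame = src.copy()
        frame["item_id"] = item_ids(module, src)
        frame = frame[frame["pin"].isin(pins)]
        if table == "Terminology" and spec.subheadings is not None:
            frame = frame[frame["subheading"].isin(spec.subheadings)]
        if not spec.include_deleted and "deleted" in frame.columns:
            frame = frame[~frame["deleted"]]
        if spec.date_range is not None and "date" in frame.columns:
            lo, hi = (pd.Timestamp(spec.date_range[0]),
                      pd.Timestamp(spec.date_range[1]))
            frame = frame[(frame["date"] >= lo) & (frame["date"] <= hi)]
        if "date" in frame.columns:
            frame = frame.sort_values("date", kind="stable")
        fields_ = spec.tables[table]
        keep = ["item_id"] + (list(fields_) if fields_ is not None
                              else MODULE_SCHEMAS[module])
        if "pin" not in keep:
            keep.insert(1, "pin")
        if module in DELETABLE_MODULES and "deleted" not in keep:
            keep.append("deleted")
        tables[table] = frame.loc[:, keep].reset_index(drop=True)
    return Register(tables=tables, caseset_pins=frozenset(pins),
                    db_fingerprint=caseset.db_fingerprint)


def extract_narrative(db: EMRDatabase, caseset: CaseSet,
                      subheadings: list[str]) -> pd.DataFrame:
    """The Terminology table alone: narrative rows of caseset patients whose
    subheading is in the selected set, date-sorted."""
    if not subheadings:
        raise ExtractionSpecError("subheading selection must be non-empty")
    src = db.modules["narrative"]
    frame = src.copy()
    frame["item_id"] = item_ids("narrative", src)
    frame = frame[frame["pin"].isin(caseset.pins)
                  & frame["subheading"].isin(subheadings)]
    frame = frame.sort_values("date", kind="stable").reset_index(drop=True)
    return frame.loc[:, ["item_id"] + MODULE_SCHEMAS["narrative"]]


def write_register(register: Register, out_dir: str | Path) -> list[Path]:
    """Write the nine tables as CSV plus a JSON provenance sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    provenance = {}
    for table, frame in register.tables.items():
        out = frame.copy()
        for c in out.columns:
            if c in ("date", "record_opened"):
                out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
            elif c in ("deleted", "alive", "fasting"):
                out[c] = out[c].map({True: "true", False: "false"})
        fp = out_dir / f"{table}.csv"
        out.to_csv(fp, index=False, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        written.append(fp)
        if "deleted" in frame.columns and len(frame):
            provenance[table] = {
                str(r["item_id"]): bool(r["deleted"]) for _, r in frame.iterrows()
            }
        else:
            provenance[table] = {}
    sp = out_dir / "provenance.json"
    sp.write_text(json.dumps(
        {"db_fingerprint": register.db_fingerprint, "deleted": provenance},
        indent=2, sort_keys=True) + "\n")
    written.append(sp)
    return written
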