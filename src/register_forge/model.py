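"""Domain model for a multi-module primary-care EMR store.

The store mirrors the module structure of a Swedish primary-care EMR system:
structured modules (contacts, diagnoses, drug prescriptions, biochemical
analyses, biometrics, documents, measurements) plus narrative journal text
organised under subheadings.  Every deletable entry type carries a ``deleted``
boolean: soft deletion hides an entry from normal views while it stays
physically stored, which is the mechanism behind both extraction-only audit
discrepancies and false-positive case inclusions.

Each module is held as a :class:`pandas.DataFrame` with a fixed schema
(:data:`MODULE_SCHEMAS`).  ``validate_database`` checks the invariants
vectorised and reports violations as data, never as exceptions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

GENDERS = ("female", "male", "unknown")
CONTACT_TYPES = ("doctor", "nurse", "telephone", "administrative")
SPECIMENS = ("blood", "plasma", "other")
DOC_TYPES = ("referral", "other")

#: column layout of every EMR module; ``date`` columns are datetime64[ns],
#: ``deleted``/``alive``/``fasting`` are bool, numeric columns are float/int.
MODULE_SCHEMAS: dict[str, list[str]] = {
    "patients": ["pin", "gender", "birth_year", "alive", "record_opened"],
    "contacts": ["pin", "date", "contact_type", "user_id", "deleted"],
    "diagnoses": ["pin", "date", "icd_version", "code", "name", "deleted"],
    "drugs": ["pin", "date", "drug_name", "atc_code", "iteration", "dosage", "deleted"],
    "labs": ["pin", "date", "analyte", "value", "unit", "fasting", "specimen", "deleted"],
    "biometrics": ["pin", "date", "weight", "height", "bmi"],
    "documents": ["pin", "date", "doc_type", "text"],
    "measurements": ["pin", "date", "name", "value", "unit"],
    "narrative": ["pin", "date", "subheading", "text"],
}

#: modules that carry a soft-deletion flag
DELETABLE_MODULES = ("contacts", "diagnoses", "drugs", "labs")

#: mapping from source module to the register table it feeds
REGISTER_TABLE_OF_MODULE = {
    "contacts": "Contacts",
    "diagnoses": "Diagnosis",
    "biometrics": "Biometrics",
    "documents": "Documents",
    "drugs": "Drugs",
    "labs": "Biochemical analysis",
    "measurements": "Measurement",
    "patients": "Patients",
    "narrative": "Terminology",
}

REGISTER_TABLES = tuple(REGISTER_TABLE_OF_MODULE[m] for m in MODULE_SCHEMAS)

_BOOL_COLUMNS = {"deleted", "alive", "fasting"}
_DATE_COLUMNS = {"date", "record_opened"}
_FLOAT_COLUMNS = {"value", "weight", "height", "bmi"}
_INT_COLUMNS = {"birth_year", "iteration", "icd_version"}


_EMPTY_TEMPLATES: dict[str, pd.DataFrame] = {}


def empty_module(module: str) -> pd.DataFrame:
    """Return an empty, schema-conformant frame for *module*."""
    if module not in _EMPTY_TEMPLATES:
        cols = MODULE_SCHEMAS[module]
        data = {}
        for c in cols:
            if c in _BOOL_COLUMNS:
                data[c] = pd.Series([], dtype=bool)
            elif c in _DATE_COLUMNS:
                data[c] = pd.Series([], dtype="datetime64[ns]")
            elif c in _FLOAT_COLUMNS:
                data[c] = pd.Series([], dtype=float)
            elif c in _INT_COLUMNS:
                data[c] = pd.Series([], dtype="int64")
            else:
                data[c] = pd.Series([], dtype=object)
        _EMPTY_TEMPLATES[module] = pd.DataFrame(data)
    return _EMPTY_TEMPLATES[module].copy()


def coerce_module(module: str, frame: pd.DataFrame) -> pd.DataFrame:
    """Coerce *frame* to the canonical dtypes of *module*; order columns."""
    cols = MODULE_SCHEMAS[module]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"module {module!r} is missing columns {missing}")
    out = frame.loc[:, cols].copy()
    for c in cols:
        if c in _BOOL_COLUMNS:
            out[c] = out[c].astype(bool)
        elif c in _DATE_COLUMNS:
            out[c] = pd.to_datetime(out[c]).astype("datetime64[ns]")
        elif c in _FLOAT_COLUMNS:
            out[c] = pd.to_numeric(out[c]).astype(float)
        elif c in _INT_COLUMNS:
            out[c] = pd.to_numeric(out[c]).astype("int64")
        else:
            out[c] = out[c].astype(object)
    return out.reset_index(drop=True)


@dataclass
class EMRDatabase:
    """A full EMR snapshot: one frame per module plus the covered period.

    ``period`` is the closed interval of dates the store covers; every entry
    date and every ``record_opened`` must fall inside it.
    """

    period: tuple[date, date]
    modules: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in MODULE_SCHEMAS:
            if m not in self.modules:
                self.modules[m] = empty_module(m)
            else:
                self.modules[m] = coerce_module(m, self.modules[m])

    @classmethod
    def empty(cls, period: tuple[date, date] = (date(1993, 1, 1), date(2005, 12, 31))) -> "EMRDatabase":
        return cls(period=period)

    @property
    def patients(self) -> pd.DataFrame:
        return self.modules["patients"]

    def __getattr__(self, name: str) -> pd.DataFrame:
        if name in MODULE_SCHEMAS:
            return self.modules[name]
        raise AttributeError(name)

    @property
    def pins(self) -> set[str]:
        return set(self.patients["pin"])

    def n_entries(self) -> dict[str, int]:
        return {m: len(f) for m, f in self.modules.items()}

    def equals(self, other: "EMRDatabase") -> bool:
        """Field-for-field equality, including deleted flags and row order."""
        if self.period != other.period:
            return False
        for m in MODULE_SCHEMAS:
            a, b = self.modules[m], other.modules[m]
            if len(a) != len(b):
                return False
            if len(a) and not a.reset_index(drop=True).equals(b.reset_index(drop=True)):
                return False
        return True

    def copy(self) -> "EMRDatabase":
        return EMRDatabase(
            period=self.period,
            modules={m: f.copy() for m, f in self.modules.items()},
        )

    def fingerprint(self) -> str:
        """Stable content hash used to tie casesets to the store they came from.

        Cached per instance; the cache is not carried across :meth:`copy`, so
        the supported mutation pattern (copy, then modify the copy) always
        re-hashes.
        """
        cached = self.__dict__.get("_fp_cache")
        if cached is not None:
            return cached
        h = hashlib.sha256()
        h.update(f"{self.period[0].isoformat()}|{self.period[1].isoformat()}".encode())
        for m in sorted(MODULE_SCHEMAS):
            f = self.modules[m]
            h.update(m.encode())
            h.update(str(len(f)).encode())
            if len(f):
                h.update(pd.util.hash_pandas_object(f, index=False).values.tobytes())
        digest = h.hexdigest()
        self.__dict__["_fp_cache"] = digest
        return digest


def item_ids(module: str, frame: pd.DataFrame) -> pd.Series:
    """Deterministic per-row item identifier: ``module:pin:date:ordinal``.

    The ordinal is the entry's rank among same-pin same-date rows of the
    module in source order, so the identifier is a stable join key between a
    register row and its source entry for the congruity audit.
    """
    if len(frame) == 0:
        return pd.Series([], dtype=object)
    if "date" in frame.columns:
        dates = pd.to_datetime(frame["date"]).dt.strftime("%Y-%m-%d")
        ordinal = frame.groupby([frame["pin"], dates]).cumcount()
    else:  # patients: one row per pin
        dates = pd.Series(["-"] * len(frame), index=frame.index)
        ordinal = frame.groupby("pin").cumcount()
    return (
        module + ":" + frame["pin"].astype(str) + ":" + dates + ":" + ordinal.astype(str)
    )


@dataclass(frozen=True)
class Violation:
    """One broken invariant: which module/row/field and the rule violated."""

    module: str
    row: int
    field: str
    rule: str
    message: str


def _ts(d: date) -> pd.Timestamp:
    return pd.Timestamp(d)


def validate_database(db: EMRDatabase) -> list[Violation]:
    """Check every model invariant; return one :class:`Violation` per breach.

    Sound and complete with respect to the documented invariants: the list is
    empty iff the store is well formed.  Violations are data, not exceptions.
    """
    out: list[Violation] = []
    start, end = _ts(db.period[0]), _ts(db.period[1])
    pats = db.patients

    dup = pats["pin"].duplicated(keep=False)
    for i in pats.index[dup]:
        out.append(Violation("patients", int(i), "pin", "unique-pin",
                             f"pin {pats.at[i, 'pin']!r} occurs more than once"))
    bad_gender = ~pats["gender"].isin(GENDERS)
    for i in pats.index[bad_gender]:
        out.append(Violation("patients", int(i), "gender", "enum",
                             f"gender {pats.at[i, 'gender']!r} not in {GENDERS}"))
    opened = pd.to_datetime(pats["record_opened"])
    bad_open = (opened < start) | (opened > end)
    for i in pats.index[bad_open]:
        out.append(Violation("patients", int(i), "record_opened", "within-period",
                             f"record_opened {opened[i].date()} outside store period"))

    known = set(pats["pin"])
    for m in MODULE_SCHEMAS:
        if m == "patients":
            continue
        f = db.modules[m]
        if len(f) == 0:
            continue
        orphan = ~f["pin"].isin(known)
        for i in f.index[orphan]:
            out.append(Violation(m, int(i), "pin", "referential-integrity",
                                 f"pin {f.at[i, 'pin']!r} absent from patients"))
        dts = pd.to_datetime(f["date"])
        bad_date = (dts < start) | (dts > end)
        for i in f.index[bad_date]:
            out.append(Violation(m, int(i), "date", "within-period",
                                 f"date {dts[i].date()} outside store period"))

    f = db.contacts
    bad = ~f["contact_type"].isin(CONTACT_TYPES)
    for i in f.index[bad]:
        out.append(Violation("contacts", int(i), "contact_type", "enum",
                             f"contact_type {f.at[i, 'contact_type']!r} not in {CONTACT_TYPES}"))

    f = db.diagnoses
    if len(f):
        empty_code = f["code"].astype(str).str.strip() == ""
        for i in f.index[empty_code]:
            out.append(Violation("diagnoses", int(i), "code", "non-empty", "empty ICD code"))
        bad_ver = ~f["icd_version"].isin((9, 10))
        for i in f.index[bad_ver]:
            out.append(Violation("diagnoses", int(i), "icd_version", "enum",
                                 f"icd_version {f.at[i, 'icd_version']!r} not 9 or 10"))
        lead = f["code"].astype(str).str.strip().str[:1]
        implied = np.where(lead.str.isdigit(), 9, np.where(lead.str.isalpha(), 10, 0))
        mismatch = (implied != 0) & (implied != f["icd_version"]) & ~empty_code & ~bad_ver
        for i in f.index[mismatch]:
            out.append(Violation("diagnoses", int(i), "icd_version", "version-syntax",
                                 f"code {f.at[i, 'code']!r} inconsistent with ICD-{f.at[i, 'icd_version']}"))

    f = db.drugs
    if len(f):
        neg = f["iteration"] < 0
        for i in f.index[neg]:
            out.append(Violation("drugs", int(i), "iteration", "non-negative",
                                 f"iteration {f.at[i, 'iteration']}"))

    f = db.labs
    if len(f):
        vals = f["value"].to_numpy(dtype=float)
        bad_val = ~np.isfinite(vals) | (vals < 0)
        for i in f.index[bad_val]:
            out.append(Violation("labs", int(i), "value", "finite-nonnegative",
                                 f"value {f.at[i, 'value']!r}"))
        bad_spec = ~f["specimen"].isin(SPECIMENS)
        for i in f.index[bad_spec]:
            out.append(Violation("labs", int(i), "specimen", "enum",
                                 f"specimen {f.at[i, 'specimen']!r} not in {SPECIMENS}"))

    f = db.biometrics
    if len(f):
        w = f["weight"].to_numpy(dtype=float)
        h = f["height"].to_numpy(dtype=float)
        b = f["bmi"].to_numpy(dtype=float)
        present = np.isfinite(w) & np.isfinite(h) & np.isfinite(b)
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = w / (h / 100.0) ** 2
        off = present & (np.abs(b - expected) > 0.1)
        for i in f.index[off]:
            out.append(Violation("biometrics", int(i), "bmi", "bmi-consistency",
                                 f"bmi {b[i]:.2f} vs weight/height implying {expected[i]:.2f}"))

    f = db.documents
    if len(f):
        bad = ~f["doc_type"].isin(DOC_TYPES)
        for i in f.index[bad]:
            out.append(Violation("documents", int(i), "doc_type", "enum",
                                 f"doc_type {f.at[i, 'doc_type']!r} not in {DOC_TYPES}"))

    return out
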