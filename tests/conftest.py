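"""Shared fixtures: hand-built small stores and randomized store builders."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from register_forge import EMRDatabase

PERIOD = (date(1993, 1, 1), date(2005, 12, 31))
PERIOD_DAYS = 4748  # days in the store period


def make_db(period=PERIOD, **modules) -> EMRDatabase:
    """Build a store from per-module lists of row dicts."""
    frames = {m: pd.DataFrame(rows) for m, rows in modules.items() if rows}
    return EMRDatabase(period=period, modules=frames)


@pytest.fixture
def small_db() -> EMRDatabase:
    """Three patients, every module populated, all invariants satisfied."""
    return make_db(
        patients=[
            {"pin": "P1", "gender": "female", "birth_year": 1940, "alive": True,
             "record_opened": "1994-03-01"},
            {"pin": "P2", "gender": "male", "birth_year": 1955, "alive": True,
             "record_opened": "1996-07-15"},
            {"pin": "P3", "gender": "male", "birth_year": 1930, "alive": False,
             "record_opened": "1993-01-10"},
        ],
        contacts=[
            {"pin": "P1", "date": "1995-05-02", "contact_type": "doctor",
             "user_id": "U3", "deleted": False},
            {"pin": "P2", "date": "1999-11-20", "contact_type": "nurse",
             "user_id": "U5", "deleted": False},
            {"pin": "P3", "date": "1993-02-01", "contact_type": "telephone",
             "user_id": "U1", "deleted": True},
        ],
        diagnoses=[
            {"pin": "P1", "date": "1998-06-01", "icd_version": 10,
             "code": "E11.9", "name": "Type 2 diabetes mellitus", "deleted": False},
            {"pin": "P2", "date": "1996-09-01", "icd_version": 9,
             "code": "401", "name": "Hypertension", "deleted": False},
        ],
        drugs=[
            {"pin": "P1", "date": "1998-06-15", "drug_name": "Metformin",
             "atc_code": "A10BA02", "iteration": 1, "dosage": "1x2", "deleted": False},
            {"pin": "P3", "date": "1994-01-05", "drug_name": "Metoprolol",
             "atc_code": "C07AB02", "iteration": 0, "dosage": "1x1", "deleted": False},
        ],
        labs=[
            {"pin": "P1", "date": "1998-05-20", "analyte": "glucose", "value": 8.4,
             "unit": "mmol/L", "fasting": True, "specimen": "plasma", "deleted": False},
            {"pin": "P2", "date": "2001-03-10", "analyte": "glucose", "value": 5.2,
             "unit": "mmol/L", "fasting": True, "specimen": "plasma", "deleted": False},
        ],
        biometrics=[
            {"pin": "P2", "date": "1997-02-01", "weight": 82.0, "height": 178.0,
             "bmi": round(82.0 / 1.78 ** 2, 2)},
        ],
        documents=[
            {"pin": "P1", "date": "1999-01-01", "doc_type": "referral",
             "text": "Referral to eye clinic."},
        ],
        measurements=[
            {"pin": "P3", "date": "1993-06-01", "name": "waist circumference",
             "value": 101.0, "unit": "cm"},
        ],
        narrative=[
            {"pin": "P1", "date": "1998-06-01", "subheading": "current disease",
             "text": "Newly diagnosed diabetes."},
            {"pin": "P2", "date": "2000-01-01", "subheading": "smoking habit",
             "text": "Non-smoker."},
        ],
    )


def random_small_db(rng: np.random.Generator, n_patients: int | None = None,
                    max_events: int = 10) -> EMRDatabase:
    """Random small store over the three criterion-bearing modules."""
    n = n_patients or int(rng.integers(2, 8))
    pins = [f"T{i}" for i in range(n)]

    def dates(k):
        return (np.datetime64("1993-01-01")
                + rng.integers(0, PERIOD_DAYS, size=k).astype("timedelta64[D]"))

    patients = pd.DataFrame({
        "pin": pins, "gender": "male", "birth_year": 1950, "alive": True,
        "record_opened": np.full(n, np.datetime64("1993-01-01")),
    })
    k = int(rng.integers(0, max_events))
    codes = rng.choice(["E11.9", "E11", "I10", "J06", "250", "4019"], size=k)
    diagnoses = pd.DataFrame({
        "pin": rng.choice(pins, size=k), "date": dates(k),
        "icd_version": [9 if c[0].isdigit() else 10 for c in codes],
        "code": codes, "name": "dx", "deleted": rng.random(k) < 0.3,
    })
    k = int(rng.integers(0, max_events))
    drugs = pd.DataFrame({
        "pin": rng.choice(pins, size=k), "date": dates(k), "drug_name": "rx",
        "atc_code": rng.choice(["A10BA02", "A10BB01", "C07AB02", "N02BE01"], size=k),
        "iteration": 0, "dosage": "1x1", "deleted": rng.random(k) < 0.3,
    })
    k = int(rng.integers(0, max_events))
    labs = pd.DataFrame({
        "pin": rng.choice(pins, size=k), "date": dates(k), "analyte": "glucose",
        "value": np.round(rng.uniform(3.5, 11.0, size=k), 1), "unit": "mmol/L",
        "fasting": rng.random(k) < 0.5,
        "specimen": rng.choice(["plasma", "blood", "other"], size=k),
        "deleted": rng.random(k) < 0.3,
    })
    return EMRDatabase(period=PERIOD, modules={
        "patients": patients, "diagnoses": diagnoses, "drugs": drugs, "labs": labs,
    })


def brute_force_flags(db: EMRDatabase, criteria) -> dict[str, dict[str, bool]]:
    """Independent per-patient linear scan implementing the case definition.

    Pure-python row loops; shares no code with the vectorised case finder.
    """
    aware = criteria.deletion_mode == "deletion_aware"
    flags: dict[str, dict[str, bool]] = {}

    def flag(pin, key):
        flags.setdefault(pin, {"by_icd": False, "by_atc": False, "by_lab": False})
        flags[pin][key] = True

    for _, row in db.diagnoses.iterrows():
        if aware and row["deleted"]:
            continue
        for version, prefix in criteria.icd_patterns:
            if row["icd_version"] == version and \
                    str(row["code"]).strip().upper().startswith(prefix.strip().upper()):
                flag(row["pin"], "by_icd")
    for _, row in db.drugs.iterrows():
        if aware and row["deleted"]:
            continue
        for prefix in criteria.atc_prefixes:
            if str(row["atc_code"]).strip().upper().startswith(prefix.strip().upper()):
                flag(row["pin"], "by_atc")
    for _, row in db.labs.iterrows():
        if aware and row["deleted"]:
            continue
        for rule in criteria.lab_rules:
            if str(row["analyte"]).strip().lower() != rule.analyte.strip().lower():
                continue
            if row["specimen"] != rule.specimen:
                continue
            if rule.require_fasting and not row["fasting"]:
                continue
            if str(row["unit"]).strip().lower() != rule.unit.strip().lower():
                continue
            ok = (row["value"] >= rule.threshold if rule.comparator == ">="
                  else row["value"] > rule.threshold)
            if ok:
                flag(row["pin"], "by_lab")
    return flags
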