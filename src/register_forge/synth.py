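"""Seeded generators of synthetic primary-care EMR stores.

Three generators cover the testing needs of the extraction pipeline:

* :func:`generate_population` — a statistically calibrated store: ~4% of
  patients are true T2DM cases who carry criterion signatures (diagnosis
  code, oral-antidiabetic prescription, elevated fasting glucose) with
  configurable documentation probabilities, on top of background clinical
  noise for everyone.  A small fraction of non-cases carry an inaccurate
  oral-antidiabetic prescription destined for soft deletion.
* :func:`generate_fixture_from_marginals` — an exact combinatorial fixture:
  a caseset whose per-criterion marginal counts and union are *exactly* the
  requested integers (printed study tables can be reproduced verbatim).
* :func:`generate_congruity_fixture` — a store engineered for the item-level
  audit: a fixed number of register items per criterion stratum, of which a
  chosen number are soft-deleted contact entries that only an extraction
  reading the physical store will emit.

All generators are deterministic under a fixed seed; separate RNG streams
are used for patients, events and deletions so that toggling deletions does
not perturb the rest of the store.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

from .model import EMRDatabase, empty_module

DEFAULT_PERIOD = (date(1993, 1, 1), date(2005, 12, 31))
DEFAULT_AUDIT_PERIODS = [
    (date(1993, 1, 1), date(1997, 12, 31)),
    (date(1998, 1, 1), date(2001, 12, 31)),
    (date(2002, 1, 1), date(2005, 12, 31)),
]

# small code catalogues; the criteria only ever touch the T2DM entries
_ICD10_BACKGROUND = [("I10", "Essential hypertension"),
                     ("J06.9", "Acute upper respiratory infection"),
                     ("M54.5", "Low back pain"),
                     ("K21.9", "Gastro-oesophageal reflux"),
                     ("F32.9", "Depressive episode")]
_ICD9_BACKGROUND = [("401", "Essential hypertension"),
                    ("460", "Acute nasopharyngitis"),
                    ("724", "Back disorder"),
                    ("530", "Oesophageal disorder"),
                    ("311", "Depressive disorder")]
_RX_BACKGROUND = [("Metoprolol", "C07AB02"), ("Paracetamol", "N02BE01"),
                  ("Simvastatin", "C10AA01"), ("Omeprazole", "A02BC01"),
                  ("Enalapril", "C09AA02")]
_RX_ORAL_ANTIDIABETIC = [("Metformin", "A10BA02"), ("Glibenclamide", "A10BB01")]
_DOSAGES = ["1x1", "1x2", "1x3", "2x2"]
_SUBHEADINGS = ["current disease", "heritage", "physical status",
                "blood pressure", "weight", "smoking habit"]

FPG_THRESHOLD = 7.0
FBG_THRESHOLD = 6.1


class ConfigurationError(ValueError):
    """Invalid synthetic-store configuration."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic population.

    Defaults emulate a single primary-health-care centre over 1993–2005 with
    10,753 opened records and a 4% T2DM prevalence.  The documentation
    probabilities are the per-case chances that a true case carries each
    criterion signature; their defaults track the marginal fractions observed
    in that setting (ICD ~53%, ATC ~38%, laboratory ~91%).
    """

    n_patients: int = 10_753
    period: tuple[date, date] = DEFAULT_PERIOD
    prevalence: float = 0.04
    p_icd_documented: float = 0.53
    p_atc_documented: float = 0.38
    p_lab_documented: float = 0.91
    #: probability a non-case carries an (inaccurate) oral-antidiabetic
    #: prescription that the caregiver later soft-deletes
    p_deleted_rx_noncase: float = 0.0012
    #: probability any contact entry is soft-deleted
    p_deleted_contact: float = 0.004
    #: exact quotas; when set they override the probabilities above
    n_deleted_rx_noncase: int | None = None
    n_deleted_contact: int | None = None
    #: background event intensities, events per patient-year
    event_rates: dict[str, float] = field(default_factory=lambda: {
        "contacts": 2.0, "diagnoses": 0.7, "drugs": 0.7, "labs": 0.9,
        "biometrics": 0.25, "documents": 0.15, "measurements": 0.15,
        "narrative": 0.4,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "prevalence": self.prevalence,
            "p_icd_documented": self.p_icd_documented,
            "p_atc_documented": self.p_atc_documented,
            "p_lab_documented": self.p_lab_documented,
            "p_deleted_rx_noncase": self.p_deleted_rx_noncase,
            "p_deleted_contact": self.p_deleted_contact,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.period[0] >= self.period[1]:
            raise ConfigurationError("period start must precede period end")
        if any(r < 0 for r in self.event_rates.values()):
            raise ConfigurationError("event rates must be >= 0")


@dataclass
class GroundTruth:
    """Per-PIN truth for a generated store.

    ``table`` is indexed by pin with columns: ``is_case``, the three
    ``planted_*`` signature flags, ``inaccurate_rx`` (non-case carrying an
    oral-antidiabetic prescription), ``rx_deleted`` and
    ``n_deleted_contacts`` (populated by :func:`inject_soft_deletions`).
    """

    table: pd.DataFrame

    @property
    def case_pins(self) -> set[str]:
        return set(self.table.index[self.table["is_case"]])

    @property
    def n_cases(self) -> int:
        return int(self.table["is_case"].sum())

    def documented_case_pins(self) -> set[str]:
        """Cases that carry at least one planted criterion signature."""
        t = self.table
        doc = t["is_case"] & (t["planted_icd"] | t["planted_atc"] | t["planted_lab"])
        return set(t.index[doc])

    def copy(self) -> "GroundTruth":
        return GroundTruth(self.table.copy())


def _empty_truth(pins: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "is_case": False, "planted_icd": False, "planted_atc": False,
            "planted_lab": False, "inaccurate_rx": False, "rx_deleted": False,
            "n_deleted_contacts": 0,
        },
        index=pd.Index(pins, name="pin"),
    )


def _d64(d: date) -> np.datetime64:
    return np.datetime64(d.isoformat())


def generate_population(config: SynthConfig) -> tuple[EMRDatabase, GroundTruth]:
    """Generate a full synthetic EMR store with planted case signatures.

    True-case status is Bernoulli(prevalence); each true case independently
    receives each of the three criterion signatures with its documentation
    probability.  Non-cases receive normoglycaemic labs and unrelated codes;
    a configurable fraction additionally receive the inaccurate
    oral-antidiabetic prescription later soft-deleted by
    :func:`inject_soft_deletions`.
    """
    rng_p, rng_e, rng_d = (np.random.default_rng(s)
                           for s in np.random.SeedSequence(config.seed).spawn(3))
    n = config.n_patients
    start = _d64(config.period[0])
    total_days = int((_d64(config.period[1]) - start).astype(int))
    pins = [f"P{i:06d}" for i in range(n)]
    truth = _empty_truth(pins)

    if n == 0:
        return EMRDatabase(period=config.period), GroundTruth(truth)

    is_case = rng_p.random(n) < config.prevalence
    gender = np.where(rng_p.random(n) < 0.52, "female", "male")
    birth_year = np.where(
        is_case,
        rng_p.integers(1918, 1961, size=n),
        rng_p.integers(1918, 1991, size=n),
    )
    alive = rng_p.random(n) < 0.93
    opened_days = rng_p.integers(0, total_days + 1, size=n)
    exposure = total_days - opened_days  # days under observation

    truth["is_case"] = is_case

    patients = pd.DataFrame({
        "pin": pins, "gender": gender, "birth_year": birth_year,
        "alive": alive,
        "record_opened": start + opened_days.astype("timedelta64[D]"),
    })

    pins_arr = np.asarray(pins, dtype=object)

    def background(rate: float):
        counts = rng_e.poisson(rate * exposure / 365.25)
        rep_pin = np.repeat(pins_arr, counts)
        rep_open = np.repeat(opened_days, counts)
        rep_exp = np.repeat(exposure, counts)
        offs = np.floor(rng_e.random(counts.sum()) * (rep_exp + 1)).astype(int)
        dates = start + (rep_open + offs).astype("timedelta64[D]")
        return rep_pin, dates

    rates = config.event_rates
    frames: dict[str, pd.DataFrame] = {"patients": patients}

    # contacts
    pin_c, date_c = background(rates["contacts"])
    m = len(pin_c)
    frames["contacts"] = pd.DataFrame({
        "pin": pin_c, "date": date_c,
        "contact_type": rng_e.choice(
            ["doctor", "nurse", "telephone", "administrative"], size=m,
            p=[0.45, 0.30, 0.15, 0.10]),
        "user_id": np.char.add("U", rng_e.integers(1, 21, size=m).astype(str)),
        "deleted": np.zeros(m, dtype=bool),
    })

    # diagnoses: background codes, ICD version switching with the calendar
    pin_dg, date_dg = background(rates["diagnoses"])
    m = len(pin_dg)
    idx = rng_e.integers(0, len(_ICD10_BACKGROUND), size=m)
    era10 = date_dg >= _d64(date(1997, 1, 1))
    code = np.where(era10,
                    [_ICD10_BACKGROUND[i][0] for i in idx],
                    [_ICD9_BACKGROUND[i][0] for i in idx])
    name = np.where(era10,
                    [_ICD10_BACKGROUND[i][1] for i in idx],
                    [_ICD9_BACKGROUND[i][1] for i in idx])
    diag = pd.DataFrame({
        "pin": pin_dg, "date": date_dg,
        "icd_version": np.where(era10, 10, 9), "code": code, "name": name,
        "deleted": np.zeros(m, dtype=bool),
    })

    # drugs: background prescriptions (never oral antidiabetics)
    pin_rx, date_rx = background(rates["drugs"])
    m = len(pin_rx)
    idx = rng_e.integers(0, len(_RX_BACKGROUND), size=m)
    drugs = pd.DataFrame({
        "pin": pin_rx, "date": date_rx,
        "drug_name": [_RX_BACKGROUND[i][0] for i in idx],
        "atc_code": [_RX_BACKGROUND[i][1] for i in idx],
        "iteration": rng_e.integers(0, 4, size=m),
        "dosage": rng_e.choice(_DOSAGES, size=m),
        "deleted": np.zeros(m, dtype=bool),
    })

    # labs: mixture of routine analytes; fasting glucose is normoglycaemic
    # for everyone here (elevated values are planted signatures below)
    pin_lb, date_lb = background(rates["labs"])
    m = len(pin_lb)
    cat = rng_e.choice(5, size=m, p=[0.25, 0.20, 0.15, 0.20, 0.20])
    value = np.empty(m)
    value[cat == 0] = rng_e.normal(140, 12, size=(cat == 0).sum())   # hemoglobin g/L
    value[cat == 1] = rng_e.normal(5.5, 1.0, size=(cat == 1).sum())  # cholesterol
    value[cat == 2] = rng_e.normal(80, 15, size=(cat == 2).sum())    # creatinine
    value[cat == 3] = rng_e.normal(6.0, 1.2, size=(cat == 3).sum())  # random glucose
    fasting = cat == 4
    specimen = np.full(m, "plasma", dtype=object)
    blood = fasting & (rng_e.random(m) < 0.3)
    specimen[blood] = "blood"
    value[fasting & ~blood] = rng_e.normal(5.0, 0.5, size=(fasting & ~blood).sum())
    value[blood] = rng_e.normal(4.5, 0.4, size=blood.sum())
    value = np.maximum(value, 0.1)
    analyte = np.where(cat == 0, "hemoglobin",
              np.where(cat == 1, "cholesterol",
              np.where(cat == 2, "creatinine", "glucose")))
    unit = np.where(cat == 0, "g/L", np.where(cat == 2, "umol/L", "mmol/L"))
    labs = pd.DataFrame({
        "pin": pin_lb, "date": date_lb, "analyte": analyte,
        "value": np.round(value, 2), "unit": unit, "fasting": fasting,
        "specimen": specimen, "deleted": np.zeros(m, dtype=bool),
    })

    # biometrics (consistent BMI), documents, measurements, narrative
    pin_bm, date_bm = background(rates["biometrics"])
    m = len(pin_bm)
    weight = np.round(rng_e.normal(78, 14, size=m).clip(40, 160), 1)
    height = np.round(rng_e.normal(171, 9, size=m).clip(145, 205), 1)
    frames["biometrics"] = pd.DataFrame({
        "pin": pin_bm, "date": date_bm, "weight": weight, "height": height,
        "bmi": np.round(weight / (height / 100.0) ** 2, 2),
    })

    pin_doc, date_doc = background(rates["documents"])
    m = len(pin_doc)
    frames["documents"] = pd.DataFrame({
        "pin": pin_doc, "date": date_doc,
        "doc_type": rng_e.choice(["referral", "other"], size=m, p=[0.4, 0.6]),
        "text": np.where(rng_e.random(m) < 0.4,
                         "Referral to specialist clinic.",
                         "Clinical note filed."),
    })

    pin_ms, date_ms = background(rates["measurements"])
    m = len(pin_ms)
    ms_name = rng_e.choice(["waist circumference", "peak expiratory flow"], size=m)
    frames["measurements"] = pd.DataFrame({
        "pin": pin_ms, "date": date_ms, "name": ms_name,
        "value": np.round(np.where(ms_name == "waist circumference",
                                   rng_e.normal(94, 12, size=m),
                                   rng_e.normal(460, 80, size=m)), 1),
        "unit": np.where(ms_name == "waist circumference", "cm", "L/min"),
    })

    pin_nr, date_nr = background(rates["narrative"])
    m = len(pin_nr)
    sub = rng_e.choice(_SUBHEADINGS, size=m)
    frames["narrative"] = pd.DataFrame({
        "pin": pin_nr, "date": date_nr, "subheading": sub,
        "text": np.char.add(np.char.add("Documented under ", sub.astype(str)), "."),
    })

    # --- planted criterion signatures for true cases -----------------------
    def signature_dates(mask: np.ndarray) -> np.ndarray:
        offs = np.floor(rng_e.random(mask.sum()) * (exposure[mask] + 1)).astype(int)
        return start + (opened_days[mask] + offs).astype("timedelta64[D]")

    planted_icd = is_case & (rng_e.random(n) < config.p_icd_documented)
    planted_atc = is_case & (rng_e.random(n) < config.p_atc_documented)
    planted_lab = is_case & (rng_e.random(n) < config.p_lab_documented)
    truth["planted_icd"] = planted_icd
    truth["planted_atc"] = planted_atc
    truth["planted_lab"] = planted_lab

    d_icd = signature_dates(planted_icd)
    era10 = d_icd >= _d64(date(1997, 1, 1))
    diag_sig = pd.DataFrame({
        "pin": pins_arr[planted_icd], "date": d_icd,
        "icd_version": np.where(era10, 10, 9),
        "code": np.where(era10, "E11.9", "250"),
        "name": "Type 2 diabetes mellitus",
        "deleted": False,
    })
    frames["diagnoses"] = pd.concat([diag, diag_sig], ignore_index=True)

    k = int(planted_atc.sum())
    idx = rng_e.integers(0, len(_RX_ORAL_ANTIDIABETIC), size=k)
    rx_sig = pd.DataFrame({
        "pin": pins_arr[planted_atc], "date": signature_dates(planted_atc),
        "drug_name": [_RX_ORAL_ANTIDIABETIC[i][0] for i in idx],
        "atc_code": [_RX_ORAL_ANTIDIABETIC[i][1] for i in idx],
        "iteration": rng_e.integers(0, 4, size=k),
        "dosage": rng_e.choice(_DOSAGES, size=k),
        "deleted": False,
    })

    k = int(planted_lab.sum())
    blood = rng_e.random(k) < 0.2
    thr = np.where(blood, FBG_THRESHOLD, FPG_THRESHOLD)
    # shifted lognormal: always above the diagnostic threshold, median thr+2
    lab_val = thr + rng_e.lognormal(np.log(2.0), 0.5, size=k)
    lab_sig = pd.DataFrame({
        "pin": pins_arr[planted_lab], "date": signature_dates(planted_lab),
        "analyte": "glucose", "value": np.round(lab_val, 1), "unit": "mmol/L",
        "fasting": True,
        "specimen": np.where(blood, "blood", "plasma"),
        "deleted": False,
    })
    frames["labs"] = pd.concat([labs, lab_sig], ignore_index=True)

    # inaccurate oral-antidiabetic prescriptions on selected non-cases
    # (deletion stream: toggling these never perturbs the rest of the store)
    noncase_idx = np.flatnonzero(~is_case)
    if config.n_deleted_rx_noncase is not None:
        if config.n_deleted_rx_noncase > len(noncase_idx):
            raise ConfigurationError("deleted-rx quota exceeds number of non-cases")
        chosen = rng_d.choice(noncase_idx, size=config.n_deleted_rx_noncase,
                              replace=False)
    else:
        chosen = noncase_idx[rng_d.random(len(noncase_idx))
                             < config.p_deleted_rx_noncase]
    chosen = np.sort(chosen)
    inaccurate = np.zeros(n, dtype=bool)
    inaccurate[chosen] = True
    truth["inaccurate_rx"] = inaccurate
    k = len(chosen)
    rx_bad = pd.DataFrame({
        "pin": pins_arr[chosen], "date": signature_dates(inaccurate),
        "drug_name": "Metformin", "atc_code": "A10BA02",
        "iteration": 0, "dosage": rng_d.choice(_DOSAGES, size=k),
        "deleted": False,
    })
    frames["drugs"] = pd.concat([drugs, rx_sig, rx_bad], ignore_index=True)

    db = EMRDatabase(period=config.period, modules=frames)
    return db, GroundTruth(truth)


def inject_soft_deletions(
    db: EMRDatabase, gt: GroundTruth, config: SynthConfig
) -> tuple[EMRDatabase, GroundTruth]:
    """Flip ``deleted`` flags: inaccurate prescriptions and contact entries.

    Marks the oral-antidiabetic prescriptions of the ground-truth-selected
    non-cases as deleted, and soft-deletes contact entries by quota or
    probability.  No entry is removed; entry counts are conserved.
    """
    db = db.copy()
    gt = gt.copy()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])

    bad_pins = set(gt.table.index[gt.table["inaccurate_rx"]])
    if bad_pins:
        drugs = db.modules["drugs"]
        mask = drugs["pin"].isin(bad_pins) & drugs["atc_code"].str.upper().str.startswith("A10B")
        drugs.loc[mask, "deleted"] = True
        gt.table.loc[list(bad_pins), "rx_deleted"] = True

    contacts = db.modules["contacts"]
    if len(contacts):
        if config.n_deleted_contact is not None:
            if config.n_deleted_contact > len(contacts):
                raise ConfigurationError("deleted-contact quota exceeds contact count")
            rows = np.sort(rng.choice(len(contacts), size=config.n_deleted_contact,
                                      replace=False))
        else:
            rows = np.flatnonzero(rng.random(len(contacts)) < config.p_deleted_contact)
        if len(rows):
            contacts.iloc[rows, contacts.columns.get_loc("deleted")] = True
            per_pin = contacts.iloc[rows]["pin"].value_counts()
            gt.table.loc[per_pin.index, "n_deleted_contacts"] = (
                gt.table.loc[per_pin.index, "n_deleted_contacts"] + per_pin
            ).astype(int)
    return db, gt


class InfeasibleMarginals(ValueError):
    """Requested marginal counts admit no three-set arrangement."""


def _memberships_from_marginals(
    total: int, n_icd: int, n_atc: int, n_lab: int,
    region_counts: tuple[int, ...] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean membership arrays (icd, atc, lab) over ``total`` patients."""
    for name, v in (("total", total), ("n_icd", n_icd), ("n_atc", n_atc), ("n_lab", n_lab)):
        if v < 0:
            raise InfeasibleMarginals(f"{name} must be >= 0")
    if max(n_icd, n_atc, n_lab) > total:
        raise InfeasibleMarginals("a marginal exceeds the union size")
    if n_icd + n_atc + n_lab < total:
        raise InfeasibleMarginals("marginals cannot cover the union")

    icd = np.zeros(total, dtype=bool)
    atc = np.zeros(total, dtype=bool)
    lab = np.zeros(total, dtype=bool)

    if region_counts is not None:
        if len(region_counts) != 7 or any(c < 0 for c in region_counts):
            raise InfeasibleMarginals("region_counts must be 7 non-negative ints")
        i_, a_, l_, ia, il, al, ial = region_counts
        if sum(region_counts) != total:
            raise InfeasibleMarginals("region counts do not sum to the union size")
        if (i_ + ia + il + ial, a_ + ia + al + ial, l_ + il + al + ial) != (n_icd, n_atc, n_lab):
            raise InfeasibleMarginals("region counts do not reproduce the marginals")
        bounds = np.cumsum([0, i_, a_, l_, ia, il, al, ial])
        blocks = [slice(bounds[k], bounds[k + 1]) for k in range(7)]
        for k, sets in enumerate([(icd,), (atc,), (lab,), (icd, atc),
                                  (icd, lab), (atc, lab), (icd, atc, lab)]):
            for s in sets:
                s[blocks[k]] = True
        return icd, atc, lab

    # greedy cover: place largest sets over the uncovered tail first, fold
    # each set's remainder back onto the head (overlap)
    sets = sorted([(n_icd, icd), (n_atc, atc), (n_lab, lab)],
                  key=lambda t: -t[0])
    covered = 0
    for size, arr in sets:
        fresh = min(size, total - covered)
        arr[covered:covered + fresh] = True
        leftover = size - fresh
        if leftover:
            arr[:leftover] = True
        covered += fresh
    return icd, atc, lab


def generate_fixture_from_marginals(
    total: int, n_icd: int, n_atc: int, n_lab: int,
    region_counts: tuple[int, ...] | None = None,
    seed: int = 0,
    period: tuple[date, date] = DEFAULT_PERIOD,
    audit_periods: list[tuple[date, date]] | None = None,
) -> tuple[EMRDatabase, GroundTruth]:
    """Build a store on which case finding yields exact marginal counts.

    Every generated patient matches at least one criterion; the per-criterion
    counts and the union are exactly the requested integers.  Qualifying
    events are spread round-robin over the audit periods so stratified
    sampling downstream has eligible patients in every stratum.
    """
    icd, atc, lab = _memberships_from_marginals(total, n_icd, n_atc, n_lab,
                                                region_counts)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(total)
    icd, atc, lab = icd[perm], atc[perm], lab[perm]

    if audit_periods is None:
        audit_periods = [(max(p0, period[0]), min(p1, period[1]))
                         for p0, p1 in DEFAULT_AUDIT_PERIODS
                         if p0 <= period[1] and p1 >= period[0]]
    pins = [f"M{i:05d}" for i in range(total)]
    pins_arr = np.asarray(pins, dtype=object)

    # patient i's qualifying events all land in audit period i mod k
    k = len(audit_periods)
    pidx = np.arange(total) % k
    p_start = np.array([_d64(p[0]) for p in audit_periods])
    p_len = np.array([int((_d64(p[1]) - _d64(p[0])).astype(int)) + 1
                      for p in audit_periods])

    def dates_for(mask: np.ndarray) -> np.ndarray:
        offs = np.floor(rng.random(mask.sum()) * p_len[pidx[mask]]).astype(int)
        return p_start[pidx[mask]] + offs.astype("timedelta64[D]")

    patients = pd.DataFrame({
        "pin": pins,
        "gender": np.where(rng.random(total) < 0.5, "female", "male"),
        "birth_year": rng.integers(1920, 1960, size=total),
        "alive": np.ones(total, dtype=bool),
        "record_opened": np.full(total, _d64(period[0])),
    })

    frames = {"patients": patients}
    d_icd = dates_for(icd)
    frames["diagnoses"] = pd.DataFrame({
        "pin": pins_arr[icd], "date": d_icd,
        "icd_version": 10, "code": "E11.9",
        "name": "Type 2 diabetes mellitus", "deleted": False,
    })
    m = int(atc.sum())
    frames["drugs"] = pd.DataFrame({
        "pin": pins_arr[atc], "date": dates_for(atc),
        "drug_name": "Metformin", "atc_code": "A10BA02",
        "iteration": 0, "dosage": "1x2", "deleted": False,
    })
    m = int(lab.sum())
    frames["labs"] = pd.DataFrame({
        "pin": pins_arr[lab], "date": dates_for(lab),
        "analyte": "glucose",
        "value": np.round(7.5 + 4.0 * rng.random(m), 1),
        "unit": "mmol/L", "fasting": True, "specimen": "plasma",
        "deleted": False,
    })

    truth = _empty_truth(pins)
    truth["is_case"] = True
    truth["planted_icd"] = icd
    truth["planted_atc"] = atc
    truth["planted_lab"] = lab
    return EMRDatabase(period=period, modules=frames), GroundTruth(truth)


def add_deleted_rx_noncases(
    db: EMRDatabase, gt: GroundTruth, n: int, seed: int = 0
) -> tuple[EMRDatabase, GroundTruth]:
    """Append *n* non-case patients whose only qualifying entry is a
    soft-deleted oral-antidiabetic prescription.

    These patients are invisible to a deletion-aware search but included by a
    deletion-blind one, so the blind−aware case-count gap grows by exactly
    *n*.
    """
    db = db.copy()
    gt = gt.copy()
    rng = np.random.default_rng(seed)
    pins = [f"X{i:05d}" for i in range(n)]
    start = _d64(db.period[0])
    total_days = int((_d64(db.period[1]) - start).astype(int))
    new_pat = pd.DataFrame({
        "pin": pins,
        "gender": np.where(rng.random(n) < 0.5, "female", "male"),
        "birth_year": rng.integers(1925, 1975, size=n),
        "alive": np.ones(n, dtype=bool),
        "record_opened": np.full(n, start),
    })
    new_rx = pd.DataFrame({
        "pin": pins,
        "date": start + rng.integers(0, total_days + 1, size=n).astype("timedelta64[D]"),
        "drug_name": "Metformin", "atc_code": "A10BA02",
        "iteration": 0, "dosage": "1x1", "deleted": True,
    })
    db.modules["patients"] = pd.concat([db.modules["patients"], new_pat],
                                       ignore_index=True)
    db.modules["drugs"] = pd.concat([db.modules["drugs"], new_rx],
                                    ignore_index=True)
    extra = _empty_truth(pins)
    extra["inaccurate_rx"] = True
    extra["rx_deleted"] = True
    gt.table = pd.concat([gt.table, extra])
    return db, gt


def generate_congruity_fixture(
    items_per_stratum: dict[str, int] | None = None,
    pins_per_criterion: int = 21,
    n_deleted_contacts: int = 13,
    seed: int = 0,
    period: tuple[date, date] = DEFAULT_PERIOD,
    audit_periods: list[tuple[date, date]] | None = None,
) -> tuple[EMRDatabase, GroundTruth]:
    """Store engineered for the item-level congruity audit.

    Each criterion stratum contributes ``pins_per_criterion`` patients whose
    register rows total exactly ``items_per_stratum[criterion]`` (counting
    one item per emitted register row, including the Patients row).  Every
    patient has rows in all nine tables.  ``n_deleted_contacts`` contact
    entries are soft-deleted: an extraction reading the physical store emits
    them, but they are absent from the non-deleted source — the
    extraction-only discrepancies the audit must surface and then resolve.
    """
    if items_per_stratum is None:
        items_per_stratum = {"icd": 1060, "atc": 1216, "lab": 769}
    if audit_periods is None:
        audit_periods = DEFAULT_AUDIT_PERIODS
    k = len(audit_periods)
    if pins_per_criterion % k:
        raise ConfigurationError(
            "pins_per_criterion must be divisible by the number of audit periods")
    rng = np.random.default_rng(seed)

    rows: dict[str, list[dict]] = {m: [] for m in
                                   ("patients", "contacts", "diagnoses", "drugs",
                                    "labs", "biometrics", "documents",
                                    "measurements", "narrative")}
    truth_rows = []
    total_contacts_planned = sum(
        items_per_stratum[c] - 8 * pins_per_criterion for c in items_per_stratum)
    if n_deleted_contacts > total_contacts_planned:
        raise ConfigurationError("deleted-contact quota exceeds planned contacts")

    contact_counter = 0
    for c_i, criterion in enumerate(("icd", "atc", "lab")):
        total_items = items_per_stratum[criterion]
        base, rem = divmod(total_items, pins_per_criterion)
        if base < 9:
            raise ConfigurationError("too few items per patient to fill nine tables")
        for j in range(pins_per_criterion):
            pin = f"A{c_i}{j:03d}"
            p = audit_periods[j // (pins_per_criterion // k)]
            p0, p1 = _d64(p[0]), _d64(p[1])
            span = int((p1 - p0).astype(int)) + 1

            def pdate() -> np.datetime64:
                return p0 + int(rng.integers(0, span))

            n_items = base + (1 if j < rem else 0)
            truth_rows.append(pin)
            rows["patients"].append({
                "pin": pin, "gender": "female" if j % 2 else "male",
                "birth_year": 1930 + j, "alive": True,
                "record_opened": _d64(period[0]),
            })
            rows["diagnoses"].append({
                "pin": pin, "date": pdate(), "icd_version": 10,
                "code": "E11.9" if criterion == "icd" else "I10",
                "name": ("Type 2 diabetes mellitus" if criterion == "icd"
                         else "Essential hypertension"),
                "deleted": False,
            })
            rows["drugs"].append({
                "pin": pin, "date": pdate(),
                "drug_name": "Metformin" if criterion == "atc" else "Metoprolol",
                "atc_code": "A10BA02" if criterion == "atc" else "C07AB02",
                "iteration": 1, "dosage": "1x2", "deleted": False,
            })
            rows["labs"].append({
                "pin": pin, "date": pdate(), "analyte": "glucose",
                "value": 9.1 if criterion == "lab" else 5.1,
                "unit": "mmol/L", "fasting": True, "specimen": "plasma",
                "deleted": False,
            })
            w, h = 80.0, 175.0
            rows["biometrics"].append({
                "pin": pin, "date": pdate(), "weight": w, "height": h,
                "bmi": round(w / (h / 100) ** 2, 2),
            })
            rows["documents"].append({
                "pin": pin, "date": pdate(), "doc_type": "referral",
                "text": "Referral to specialist clinic.",
            })
            rows["measurements"].append({
                "pin": pin, "date": pdate(), "name": "waist circumference",
                "value": 95.0, "unit": "cm",
            })
            rows["narrative"].append({
                "pin": pin, "date": pdate(), "subheading": "current disease",
                "text": "Stable on current regimen.",
            })
            for _ in range(n_items - 8):
                rows["contacts"].append({
                    "pin": pin, "date": pdate(),
                    "contact_type": "doctor" if contact_counter % 3 else "nurse",
                    "user_id": f"U{(contact_counter % 9) + 1}",
                    "deleted": contact_counter < n_deleted_contacts,
                })
                contact_counter += 1

    frames = {m: pd.DataFrame(r) for m, r in rows.items()}
    db = EMRDatabase(period=period, modules=frames)
    truth = _empty_truth(truth_rows)
    truth["is_case"] = True
    for c_i, criterion in enumerate(("icd", "atc", "lab")):
        sel = [p for p in truth_rows if p.startswith(f"A{c_i}")]
        truth.loc[sel, f"planted_{criterion}"] = True
    return db, GroundTruth(truth)
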