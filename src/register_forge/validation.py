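"""Validation protocol for the two-step extraction.

Mirrors a chart-review style evaluation: stratified random sampling of
patients for a manual audit (per inclusion criterion and calendar period,
with cross-step exclusion so no patient is audited twice), an item-level
congruity audit of the extracted register against its source (classifying
every item by *occurrence* — is it present at all — and *coherence* — are
the field values equal), diagnostic accuracy of one caseset against a
reference caseset, the Venn partition of the three inclusion criteria, and
prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .casefind import CaseSet, InclusionCriteria, _active, _norm_codes
from .extract import Register, _MODULE_OF_TABLE
from .model import EMRDatabase, item_ids
from .synth import DEFAULT_AUDIT_PERIODS

CRITERIA = ("icd", "lab", "atc")  # audit step order: A, B, C


def round_percent(x: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up to *ndigits* decimals (97.303 → 97.3)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(100.0 * x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# stratified audit sampling
# ---------------------------------------------------------------------------

@dataclass
class SamplingPlan:
    """Stratified audit sampling plan.

    Per criterion (in ``criterion_order``), the criterion's patients are
    shuffled with the seeded RNG and assigned to the calendar period of
    their first qualifying event; the first ``pins_per_stratum`` per period
    are taken.  Patients selected in an earlier step are excluded from later
    steps.
    """

    pins_per_stratum: int = 7
    periods: list[tuple[date, date]] = field(
        default_factory=lambda: list(DEFAULT_AUDIT_PERIODS))
    criterion_order: tuple[str, ...] = CRITERIA
    seed: int = 0
    #: when True the congruity audit only examines records dated within the
    #: period the patient was sampled for, instead of the whole record
    restrict_to_period: bool = False

    def __post_init__(self) -> None:
        if self.pins_per_stratum < 1:
            raise ValueError("pins_per_stratum must be >= 1")
        for (a0, a1), (b0, b1) in zip(self.periods, self.periods[1:]):
            if not (a0 <= a1 < b0 <= b1):
                raise ValueError("periods must be disjoint and ordered")
        if set(self.criterion_order) - set(CRITERIA):
            raise ValueError(f"criteria must be among {CRITERIA}")


@dataclass
class AuditSample:
    """Ordered audit selections plus the exclusion/shortfall log."""

    selections: pd.DataFrame  # columns: criterion, period_index, pin, first_event
    log: list[str] = field(default_factory=list)

    @property
    def pins(self) -> set[str]:
        return set(self.selections["pin"])

    def pins_by_criterion(self, criterion: str) -> set[str]:
        sel = self.selections
        return set(sel.loc[sel["criterion"] == criterion, "pin"])

    def __len__(self) -> int:
        return len(self.selections)


def _first_event_dates(db: EMRDatabase, criteria: InclusionCriteria,
                       criterion: str) -> pd.Series:
    """First qualifying event date per pin for one criterion family."""
    mode = criteria.deletion_mode
    if criterion == "icd":
        f = _active(db.diagnoses, mode)
        codes = _norm_codes(f["code"]) if len(f) else pd.Series(dtype=object)
        hit = pd.Series(False, index=f.index)
        for version, prefix in criteria.icd_patterns:
            hit |= (f["icd_version"] == version) & codes.str.startswith(prefix.strip().upper())
    elif criterion == "atc":
        f = _active(db.drugs, mode)
        codes = _norm_codes(f["atc_code"]) if len(f) else pd.Series(dtype=object)
        hit = pd.Series(False, index=f.index)
        for prefix in criteria.atc_prefixes:
            hit |= codes.str.startswith(prefix.strip().upper())
    elif criterion == "lab":
        f = _active(db.labs, mode)
        analytes = f["analyte"].astype(str).str.strip().str.lower()
        hit = pd.Series(False, index=f.index)
        for rule in criteria.lab_rules:
            sel = (analytes == rule.analyte.strip().lower()) & (f["specimen"] == rule.specimen)
            if rule.require_fasting:
                sel &= f["fasting"]
            sel &= f["unit"].astype(str).str.strip().str.lower() == rule.unit.strip().lower()
            sel &= (f["value"] >= rule.threshold if rule.comparator == ">="
                    else f["value"] > rule.threshold)
            hit |= sel
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    matched = f[hit]
    if len(matched) == 0:
        return pd.Series(dtype="datetime64[ns]")
    return matched.groupby("pin")["date"].min()


def select_audit_sample(caseset: CaseSet, db: EMRDatabase,
                        plan: SamplingPlan) -> AuditSample:
    """Draw the stratified audit sample.

    Fully reproducible under a fixed seed; shortfalls (a stratum with fewer
    eligible patients than requested) produce a partial sample with an
    explicit warning, never silently.
    """
    rng = np.random.default_rng(plan.seed)
    periods = [(pd.Timestamp(p0), pd.Timestamp(p1)) for p0, p1 in plan.periods]
    selected: set[str] = set()
    records = []
    log: list[str] = []
    for criterion in plan.criterion_order:
        eligible = sorted(caseset.pins_by(criterion) - selected)
        excluded = caseset.pins_by(criterion) & selected
        if excluded:
            log.append(f"{criterion}: excluded {len(excluded)} previously selected PIN(s)")
        first_event = _first_event_dates(db, caseset.criteria, criterion)
        order = rng.permutation(len(eligible))
        quota = {i: plan.pins_per_stratum for i in range(len(periods))}
        for k in order:
            pin = eligible[k]
            if pin not in first_event.index:
                continue
            ev = first_event[pin]
            for i, (p0, p1) in enumerate(periods):
                if p0 <= ev <= p1 and quota[i] > 0:
                    quota[i] -= 1
                    records.append({"criterion": criterion, "period_index": i,
                                    "pin": pin, "first_event": ev})
                    selected.add(pin)
                    break
        for i, left in quota.items():
            if left > 0:
                msg = (f"stratum ({criterion}, period {i}) short by {left} "
                       f"of {plan.pins_per_stratum} PIN(s)")
                log.append(msg)
                warnings.warn(msg, stacklevel=2)
    sel = pd.DataFrame(records, columns=["criterion", "period_index", "pin",
                                         "first_event"])
    return AuditSample(selections=sel, log=log)


# ---------------------------------------------------------------------------
# item-level congruity audit
# ---------------------------------------------------------------------------

@dataclass
class CongruityReport:
    """Outcome of the item-level audit.

    Every register item of the sampled patients is classified exactly once:
    ``matched`` (present in the non-deleted source with equal field values),
    ``source_only`` (present but with a field-value mismatch), or
    ``extraction_only`` (absent from the non-deleted source).  The
    post-audit rate re-matches extraction-only items against soft-deleted
    source entries, emulating a review with administrator access.
    """

    n_compared: int
    n_matched: int
    n_source_only: int
    n_extraction_only: int
    n_resolved_deleted: int
    per_table: pd.DataFrame
    per_criterion: pd.DataFrame
    mismatches: list[dict] = field(default_factory=list)

    @property
    def congruity_rate(self) -> float:
        return self.n_matched / self.n_compared if self.n_compared else 1.0

    @property
    def post_audit_rate(self) -> float:
        if not self.n_compared:
            return 1.0
        return (self.n_matched + self.n_resolved_deleted) / self.n_compared


def _values_equal(a, b) -> bool:
    if isinstance(a, float) or isinstance(b, float):
        try:
            fa, fb = float(a), float(b)
        except (TypeError, ValueError):
            return False
        if np.isnan(fa) and np.isnan(fb):
            return True
        return abs(fa - fb) <= 1e-9 * max(1.0, abs(fa), abs(fb))
    if isinstance(a, str) and isinstance(b, str):
        return a.strip() == b.strip()
    return a == b


def compare_items(register: Register, db: EMRDatabase, sample: AuditSample,
                  plan: SamplingPlan | None = None) -> CongruityReport:
    """Audit every register item of the sampled patients against the store.

    Exhaustive: the number of classified items equals the number of register
    rows belonging to sampled patients.  When the plan's
    ``restrict_to_period`` switch is set, only dated rows falling inside the
    period each patient was sampled for are audited (undated Patients rows
    are always audited).
    """
    sampled = sample.pins
    pin_criterion = dict(zip(sample.selections["pin"],
                             sample.selections["criterion"]))
    pin_period: dict[str, tuple[pd.Timestamp, pd.Timestamp]] | None = None
    if plan is not None and plan.restrict_to_period:
        pin_period = {
            row["pin"]: (pd.Timestamp(plan.periods[row["period_index"]][0]),
                         pd.Timestamp(plan.periods[row["period_index"]][1]))
            for _, row in sample.selections.iterrows()
        }
    table_rows = []
    crit_counts: dict[str, dict[str, int]] = {}
    totals = {"compared": 0, "matched": 0, "source_only": 0,
              "extraction_only": 0, "resolved": 0}
    mismatches: list[dict] = []

    for table, reg in register.tables.items():
        module = _MODULE_OF_TABLE[table]
        src = db.modules[module].copy()
        src["item_id"] = item_ids(module, db.modules[module])
        part = reg[reg["pin"].isin(sampled)]
        if pin_period is not None and "date" in part.columns and len(part):
            lo = part["pin"].map(lambda p: pin_period[p][0])
            hi = part["pin"].map(lambda p: pin_period[p][1])
            part = part[(part["date"] >= lo) & (part["date"] <= hi)]
        n_matched = n_mismatch = n_extraction_only = n_resolved = 0
        if len(part):
            if "deleted" in src.columns:
                live = src[~src["deleted"]].set_index("item_id")
                dead = src[src["deleted"]].set_index("item_id")
            else:
                live = src.set_index("item_id")
                dead = src.iloc[0:0].set_index("item_id")
            compare_cols = [c for c in part.columns
                            if c not in ("item_id", "deleted") and c in live.columns]
            for _, row in part.iterrows():
                iid = row["item_id"]
                target = None
                in_live = iid in live.index
                if in_live:
                    target = live.loc[iid]
                if target is None:
                    n_extraction_only += 1
                    if iid in dead.index and all(
                            _values_equal(row[c], dead.loc[iid][c])
                            for c in compare_cols):
                        n_resolved += 1
                    cls = "extraction_only"
                else:
                    diffs = [c for c in compare_cols
                             if not _values_equal(row[c], target[c])]
                    if diffs:
                        n_mismatch += 1
                        mismatches.append({"table": table, "item_id": iid,
                                           "fields": diffs})
                        cls = "source_only"
                    else:
                        n_matched += 1
                        cls = "matched"
                crit = pin_criterion.get(row["pin"], "unknown")
                crit_counts.setdefault(crit, {"compared": 0})["compared"] += 1
        n_compared = len(part)
        table_rows.append({"table": table, "n_compared": n_compared,
                           "n_matched": n_matched, "n_source_only": n_mismatch,
                           "n_extraction_only": n_extraction_only,
                           "n_resolved_deleted": n_resolved})
        totals["compared"] += n_compared
        totals["matched"] += n_matched
        totals["source_only"] += n_mismatch
        totals["extraction_only"] += n_extraction_only
        totals["resolved"] += n_resolved

    per_criterion = pd.DataFrame(
        [{"criterion": c, "n_compared": d["compared"]}
         for c, d in sorted(crit_counts.items())],
        columns=["criterion", "n_compared"])
    return CongruityReport(
        n_compared=totals["compared"], n_matched=totals["matched"],
        n_source_only=totals["source_only"],
        n_extraction_only=totals["extraction_only"],
        n_resolved_deleted=totals["resolved"],
        per_table=pd.DataFrame(table_rows),
        per_criterion=per_criterion,
        mismatches=mismatches,
    )


# ---------------------------------------------------------------------------
# diagnostic accuracy, Venn partition, prevalence
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticMetrics:
    """Confusion counts and the four accuracy proportions (exact ratios)."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_total: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else 1.0

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else 1.0

    def as_percent(self, ndigits: int = 1) -> dict[str, float]:
        return {
            "sensitivity": round_percent(self.sensitivity, ndigits),
            "specificity": round_percent(self.specificity, ndigits),
            "ppv": round_percent(self.ppv, ndigits),
            "npv": round_percent(self.npv, ndigits),
        }


def _as_pins(obj) -> set[str]:
    return obj.pins if isinstance(obj, CaseSet) else set(obj)


def compute_diagnostic_metrics(test_caseset, reference_caseset,
                               n_total: int) -> DiagnosticMetrics:
    """Confusion matrix of a test caseset against a reference over a
    population of ``n_total`` patients (reference treated as truth)."""
    test, ref = _as_pins(test_caseset), _as_pins(reference_caseset)
    if n_total < len(test | ref):
        raise ValueError("n_total smaller than the union of the two casesets")
    tp = len(test & ref)
    fp = len(test - ref)
    fn = len(ref - test)
    tn = n_total - tp - fp - fn
    return DiagnosticMetrics(tp=tp, fp=fp, fn=fn, tn=tn, n_total=n_total)


_REGIONS = ("icd_only", "atc_only", "lab_only", "icd_atc", "icd_lab",
            "atc_lab", "all_three")


@dataclass
class VennPartition:
    """Counts for the seven regions of the three-criterion Venn diagram."""

    regions: dict[str, int]

    @property
    def union(self) -> int:
        return sum(self.regions.values())

    def marginals(self) -> dict[str, int]:
        r = self.regions
        return {
            "icd": r["icd_only"] + r["icd_atc"] + r["icd_lab"] + r["all_three"],
            "atc": r["atc_only"] + r["icd_atc"] + r["atc_lab"] + r["all_three"],
            "lab": r["lab_only"] + r["icd_lab"] + r["atc_lab"] + r["all_three"],
        }


def compute_venn_partition(caseset: CaseSet) -> VennPartition:
    """Partition the caseset by its per-criterion flag combination."""
    f = caseset.flags
    i, a, l = f["by_icd"], f["by_atc"], f["by_lab"]
    regions = {
        "icd_only": int((i & ~a & ~l).sum()),
        "atc_only": int((~i & a & ~l).sum()),
        "lab_only": int((~i & ~a & l).sum()),
        "icd_atc": int((i & a & ~l).sum()),
        "icd_lab": int((i & ~a & l).sum()),
        "atc_lab": int((~i & a & l).sum()),
        "all_three": int((i & a & l).sum()),
    }
    return VennPartition(regions=regions)


def compute_prevalence(reference_caseset, n_total: int) -> float:
    """Caseset size over population size; raises when n_total is zero."""
    if n_total <= 0:
        raise ValueError("prevalence undefined for an empty population")
    ref = _as_pins(reference_caseset)
    return len(ref) / n_total
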