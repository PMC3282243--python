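"""Step 1 of the extraction: rule-based case finding.

A patient record is included when at least one of three criterion families
matches: an ICD diagnostic code (version-qualified prefix), a drug
prescription (ATC prefix), or a fasting glucose concentration above the WHO
diagnostic threshold.  Two deletion-handling semantics are supported:

``deletion_blind``
    soft-deleted entries still count towards inclusion (the behaviour of an
    extraction tool reading the physical store directly);
``deletion_aware``
    soft-deleted entries are ignored (the behaviour of an EMR-integrated
    search engine that honours caregiver deletions).

The blind caseset is always a superset of the aware one, so the excess of
blind over aware counts the false-positive inclusions caused by deleted
entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .model import EMRDatabase

DELETION_MODES = ("deletion_blind", "deletion_aware")

# WHO 1999 diagnostic thresholds for diabetes mellitus, fasting samples.
FPG_THRESHOLD_MMOL_L = 7.0   # venous plasma
FBG_THRESHOLD_MMOL_L = 6.1   # whole blood


@dataclass(frozen=True)
class LabRule:
    """One laboratory inclusion rule, e.g. fasting plasma glucose >= 7.0 mmol/L."""

    analyte: str
    specimen: str            # "blood" or "plasma"
    comparator: str          # ">=" or ">"
    threshold: float
    unit: str = "mmol/L"
    require_fasting: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("lab rule threshold must be > 0")
        if self.comparator not in (">=", ">"):
            raise ValueError(f"unsupported comparator {self.comparator!r}")
        if self.specimen not in ("blood", "plasma"):
            raise ValueError(f"lab rule specimen must be blood or plasma, got {self.specimen!r}")


def default_lab_rules() -> list[LabRule]:
    """Fasting plasma/whole-blood glucose at the WHO diagnostic cut-offs."""
    return [
        LabRule("glucose", "plasma", ">=", FPG_THRESHOLD_MMOL_L),
        LabRule("glucose", "blood", ">=", FBG_THRESHOLD_MMOL_L),
    ]


@dataclass
class InclusionCriteria:
    """Declarative case definition for the three criterion families.

    ``icd_patterns`` is a list of ``(icd_version, code_prefix)`` pairs;
    matching is case-insensitive and whitespace-trimmed, by prefix.
    """

    icd_patterns: list[tuple[int, str]] = field(
        default_factory=lambda: [(10, "E11"), (9, "250")])
    atc_prefixes: list[str] = field(default_factory=lambda: ["A10B"])
    lab_rules: list[LabRule] = field(default_factory=default_lab_rules)
    deletion_mode: str = "deletion_aware"

    def __post_init__(self) -> None:
        if self.deletion_mode not in DELETION_MODES:
            raise ValueError(f"deletion_mode must be one of {DELETION_MODES}")
        if not (self.icd_patterns or self.atc_prefixes or self.lab_rules):
            raise ValueError("at least one criterion family must be non-empty")

    def with_mode(self, mode: str) -> "InclusionCriteria":
        return InclusionCriteria(
            icd_patterns=list(self.icd_patterns),
            atc_prefixes=list(self.atc_prefixes),
            lab_rules=list(self.lab_rules),
            deletion_mode=mode,
        )


@dataclass
class CaseSet:
    """Per-PIN criterion flags for every included record (the Venn substrate).

    ``flags`` is indexed by pin with boolean columns ``by_icd``, ``by_atc``,
    ``by_lab``; every included pin has at least one flag set.
    """

    flags: pd.DataFrame
    criteria: InclusionCriteria
    db_fingerprint: str

    def __len__(self) -> int:
        return len(self.flags)

    @property
    def pins(self) -> set[str]:
        return set(self.flags.index)

    def pins_by(self, criterion: str) -> set[str]:
        """Pins flagged by one criterion family ('icd' | 'atc' | 'lab')."""
        col = f"by_{criterion}"
        return set(self.flags.index[self.flags[col]])

    def counts(self) -> dict[str, int]:
        return {
            "total": len(self.flags),
            "icd": int(self.flags["by_icd"].sum()),
            "atc": int(self.flags["by_atc"].sum()),
            "lab": int(self.flags["by_lab"].sum()),
        }


class CriterionSkipped(Exception):
    """Signals that a criterion family has no rules and was not evaluated."""


def _active(frame: pd.DataFrame, mode: str) -> pd.DataFrame:
    if mode == "deletion_aware" and "deleted" in frame.columns:
        return frame[~frame["deleted"]]
    return frame


def _norm_codes(col: pd.Series) -> pd.Series:
    return col.astype(str).str.strip().str.upper()


def evaluate_icd_criterion(db: EMRDatabase, criteria: InclusionCriteria) -> set[str]:
    """Pins with a diagnosis matching any version-qualified ICD prefix."""
    if not criteria.icd_patterns:
        raise CriterionSkipped("no ICD patterns configured")
    f = _active(db.diagnoses, criteria.deletion_mode)
    if len(f) == 0:
        return set()
    codes = _norm_codes(f["code"])
    hit = pd.Series(False, index=f.index)
    for version, prefix in criteria.icd_patterns:
        hit |= (f["icd_version"] == version) & codes.str.startswith(prefix.strip().upper())
    return set(f.loc[hit, "pin"])


def evaluate_atc_criterion(db: EMRDatabase, criteria: InclusionCriteria) -> set[str]:
    """Pins with a prescription whose ATC code matches any configured prefix."""
    if not criteria.atc_prefixes:
        raise CriterionSkipped("no ATC prefixes configured")
    f = _active(db.drugs, criteria.deletion_mode)
    if len(f) == 0:
        return set()
    codes = _norm_codes(f["atc_code"])
    hit = pd.Series(False, index=f.index)
    for prefix in criteria.atc_prefixes:
        hit |= codes.str.startswith(prefix.strip().upper())
    return set(f.loc[hit, "pin"])


def evaluate_lab_criterion(db: EMRDatabase, criteria: InclusionCriteria) -> set[str]:
    """Pins with a laboratory value satisfying any rule.

    An entry must match the rule's analyte (case-insensitive), specimen and
    fasting requirement; entries whose unit differs from the rule's unit are
    skipped with a warning rather than compared on incompatible scales.
    """
    if not criteria.lab_rules:
        raise CriterionSkipped("no lab rules configured")
    f = _active(db.labs, criteria.deletion_mode)
    if len(f) == 0:
        return set()
    analytes = f["analyte"].astype(str).str.strip().str.lower()
    units = f["unit"].astype(str).str.strip()
    hit = pd.Series(False, index=f.index)
    for rule in criteria.lab_rules:
        sel = (analytes == rule.analyte.strip().lower()) & (f["specimen"] == rule.specimen)
        if rule.require_fasting:
            sel &= f["fasting"]
        unit_bad = sel & (units.str.lower() != rule.unit.strip().lower())
        if unit_bad.any():
            warnings.warn(
                f"{int(unit_bad.sum())} {rule.analyte} entries skipped: unit differs "
                f"from rule unit {rule.unit!r}", stacklevel=2)
            sel &= ~unit_bad
        if rule.comparator == ">=":
            sel &= f["value"] >= rule.threshold
        else:
            sel &= f["value"] > rule.threshold
        hit |= sel
    return set(f.loc[hit, "pin"])


def find_cases(db: EMRDatabase, criteria: InclusionCriteria) -> CaseSet:
    """Union of the three criterion evaluations, with per-criterion flags."""
    evaluators = {
        "by_icd": (evaluate_icd_criterion, criteria.icd_patterns),
        "by_atc": (evaluate_atc_criterion, criteria.atc_prefixes),
        "by_lab": (evaluate_lab_criterion, criteria.lab_rules),
    }
    hits: dict[str, set[str]] = {}
    for col, (fn, rules) in evaluators.items():
        hits[col] = fn(db, criteria) if rules else set()
    union = sorted(hits["by_icd"] | hits["by_atc"] | hits["by_lab"])
    flags = pd.DataFrame(
        {col: [pin in pins for pin in union] for col, pins in hits.items()},
        index=pd.Index(union, name="pin"),
    )
    return CaseSet(flags=flags, criteria=criteria, db_fingerprint=db.fingerprint())
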