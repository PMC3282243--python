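# register-forge

Rule-based case finding and register construction from primary-care
electronic medical records (EMRs), together with the validation protocol a
register built this way needs: stratified chart-review sampling, an
item-level congruity audit, and diagnostic accuracy against a reference
extraction.

## The problem

Primary-care EMR systems store patient data in structured modules
(diagnoses, prescriptions, laboratory results, contacts, …) and in
narrative journal text organised under subheadings. Building a research
register from such a store is a two-step extraction:

1. **Case finding** — identify the patient identification numbers (PINs)
   whose records meet at least one inclusion criterion. For a type 2
   diabetes mellitus (T2DM) register the criteria are:
   an ICD-9/ICD-10 diagnostic code of T2DM (prefixes `250` / `E11`), a
   prescription of an oral antidiabetic agent (ATC prefix `A10B`), or a
   fasting glucose concentration at or above the WHO diagnostic cut-off
   (plasma ≥ 7.0 mmol/L, whole blood ≥ 6.1 mmol/L).
2. **Register extraction** — materialise the selected data of those PINs
   into nine tables (Contacts, Diagnosis, Biometrics, Documents, Drugs,
   Biochemical analysis, Measurement, Patients, Terminology), each row
   date-sorted and traceable to its source entry.

The subtlety that makes validation interesting is **soft deletion**: a
caregiver can delete an entry so that it disappears from normal views while
remaining physically stored. A tool that reads the physical store
(*deletion-blind*) will include patients and emit items that an
EMR-integrated search engine (*deletion-aware*) never sees. The package
models both semantics, so the excess of blind over aware counts is exactly
the false-positive load caused by deleted entries, and deleted items
surface in the audit as *extraction-only* discrepancies.

The validation protocol quantifies this with standard diagnostic accuracy
measures against the deletion-aware reference —

    sensitivity = TP/(TP+FN)    specificity = TN/(TN+FP)
    PPV = TP/(TP+FP)            NPV = TN/(TN+FN)

— and with a congruity rate at single-item level: for a stratified audit
sample (by default 7 PINs × 3 calendar periods × 3 criteria, with
cross-step exclusion so no PIN is audited twice), every extracted item is
classified by *occurrence* (is it in the source at all) and *coherence*
(are the field values equal), and the congruity rate is the matched
fraction.

Because no real EMR store can ship with the package, a seeded synthetic
generator (`generate_population`) emulates a single health centre —
by default 10,753 records opened over 1993–2005 with 4% T2DM prevalence —
including criterion signatures planted with configurable documentation
probabilities, soft-deleted inaccurate prescriptions on non-cases, and
soft-deleted contact entries. Exact combinatorial fixtures
(`generate_fixture_from_marginals`, `generate_congruity_fixture`) reproduce
any printed marginal table or audit bookkeeping verbatim.

## Worked example

```python
from register_forge import (
    InclusionCriteria, add_deleted_rx_noncases, compute_diagnostic_metrics,
    compute_prevalence, find_cases, generate_fixture_from_marginals,
    round_percent,
)

# a store whose deletion-aware caseset has the reference marginals,
# plus 12 non-cases carrying only a soft-deleted oral-antidiabetic script
db, gt = generate_fixture_from_marginals(433, 231, 161, 404, seed=0)
db, gt = add_deleted_rx_noncases(db, gt, 12, seed=1)

criteria = InclusionCriteria()
blind = find_cases(db, criteria.with_mode("deletion_blind"))
aware = find_cases(db, criteria.with_mode("deletion_aware"))

print("cases (deletion-blind): ", len(blind))
print("cases (deletion-aware): ", len(aware))
print("metrics vs reference:   ",
      compute_diagnostic_metrics(blind, aware, 10_753).as_percent())
print("prevalence:             ",
      round_percent(compute_prevalence(aware, 10_753)), "%")
```

prints

```
cases (deletion-blind):  445
cases (deletion-aware):  433
metrics vs reference:    {'sensitivity': 100.0, 'specificity': 99.9, 'ppv': 97.3, 'npv': 100.0}
prevalence:              4.0 %
```

The deletion-blind extraction finds all 433 reference cases (sensitivity
100%) plus the 12 patients whose only qualifying entry was soft-deleted:
12 false positives among 10,320 non-cases is a specificity of 99.9%, and
433 true positives among 445 included is a PPV of 97.3%. The reference
caseset over the 10,753 opened records gives a T2DM prevalence of 4.0%.

A full pipeline (synthesise → case-find in both modes → extract → audit →
report) is available as a library call (`run_pipeline`) or from the shell:

```sh
register-forge synth --out-dir store --seed 3
register-forge find-cases --db store --mode deletion_blind --out caseset.json
register-forge extract --db store --caseset caseset.json --include-deleted --out-dir register
register-forge validate --db store --seed 3 --report report.json
```

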