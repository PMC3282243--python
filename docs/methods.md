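# Methods

## Data model

An EMR store is a set of nine module tables sharing a patient key (PIN):
patients, contacts, diagnoses, drugs, laboratory analyses, biometrics,
documents, measurements, and narrative text under subheadings. Each module
is a pandas DataFrame with a fixed schema; the four modules whose entries a
caregiver can retract (contacts, diagnoses, drugs, labs) carry a `deleted`
boolean. Soft deletion is a flag, never a row removal: deleted data remain
physically present, which is what lets a deletion-blind extraction see
them.

Invariants (PIN uniqueness and referential integrity, dates within the
store period, enumerated categories, ICD code syntax consistent with its
version, non-negative lab concentrations, BMI within 0.1 kg/m² of
weight/height²) are checked by `validate_database`, which reports
violations as data rather than raising, so a quality audit can enumerate
problems.

On disk a store is one CSV per module plus a JSON manifest (period, row
counts, schema version), ISO-8601 dates, `true`/`false` booleans, UTF-8.
The representation is diffable and language-neutral, and write→load is the
identity, including deleted flags. Ages are derived from birth year at a
reference date rather than stored, avoiding staleness.

Every entry has a deterministic item identifier
`module:pin:date:ordinal-within-day`, the join key that ties a register row
back to its source entry during the audit.

## Case definition

A patient is a case when at least one criterion family matches:

* **ICD** — a diagnosis whose code starts with a configured
  version-qualified prefix. Defaults: ICD-10 `E11`, ICD-9 `250`.
* **ATC** — a prescription whose ATC code starts with a configured prefix.
  Default: `A10B` (oral blood-glucose-lowering drugs).
* **Laboratory** — a fasting glucose at or above the WHO 1999 diagnostic
  cut-off: plasma ≥ 7.0 mmol/L or whole blood ≥ 6.1 mmol/L. The comparator
  is inclusive (≥); a single qualifying value suffices, with no
  confirmatory repeat. Entries whose unit differs from the rule's unit are
  skipped with a warning rather than compared across scales. Fasting status
  must be explicitly recorded; it is not inferred.

Code matching is case-insensitive and whitespace-trimmed. All lists,
thresholds and comparators are configurable; the defaults above are the
field-standard choices for a T2DM phenotype.

Two deletion-handling modes are first-class: `deletion_blind` counts
soft-deleted entries towards inclusion (physical-store semantics) and
`deletion_aware` ignores them (integrated-search semantics). Blind ⊇ aware
holds on every store, so the count gap is a direct measure of
deletion-caused false inclusions.

## Register extraction

Step 2 copies the selected fields of every module into nine tables for
exactly the caseset's PINs, stably sorted by date (ties keep source order);
the Patients table is one undated row per PIN. `include_deleted=True`
reproduces the physical-store behaviour: soft-deleted rows are emitted but
keep a `deleted` provenance mark. The narrative (Terminology) table is
filtered to selected subheadings; `None` means all subheadings present,
while an explicitly empty selection is rejected as a specification error.
A register refuses to be built against a store other than the one the
caseset was computed from (content fingerprint check).

## Validation protocol

**Sampling.** For each criterion in order (ICD, laboratory, ATC), the
criterion's PINs are shuffled with a seeded RNG and assigned to the
calendar period (defaults 1993–1997, 1998–2001, 2002–2005) containing the
PIN's first qualifying event; the first 7 per period are taken, and PINs
selected in an earlier step are excluded before each later step. The
default yields 63 distinct PINs, 21 per criterion, for any seed whenever
the strata suffice; shortfalls produce a partial sample with an explicit
warning. The stratification is interpreted as "a PIN belongs to the period
of its first qualifying event"; the alternative reading — audit only the
records dated within that period — is available behind
`SamplingPlan(restrict_to_period=True)`. The first interpretation is the
default because it audits whole records, which matches an audit whose every
sampled record contains data from all nine tables.

**Congruity.** Every register item of the sampled PINs is classified
exactly once: *matched* (present among non-deleted source entries with
equal field values — "occurrence" and "coherence"), *source-only* (present
but a field differs; the diff is recorded), or *extraction-only* (absent
from the non-deleted source). Coherence is field-value equality after
whitespace normalisation, with a relative tolerance of 1e-9 for numbers.
One register row counts as one item, including the Patients row — this
counting rule is what makes the audit bookkeeping exact. The post-audit
rate re-matches extraction-only items against soft-deleted source entries,
emulating a reviewer with administrator access to deleted data.

**Accuracy, Venn, prevalence.** Diagnostic metrics are the exact confusion
ratios of a test caseset against a reference caseset over a population of
`n_total` patients; the deletion-aware caseset plays the reference role.
The Venn partition splits a caseset into the seven regions of the
three-criterion diagram (numeric only; no diagram is drawn). Prevalence is
the reference caseset size over the population. Percentages are reported
raw and rounded half-up to one decimal (marginal fractions of the blind
tool to whole percent, matching the convention of the setting being
emulated).

## Synthetic data

`generate_population` emulates a single primary-health-care centre:
10,753 records opened uniformly over 1993–2005, T2DM prevalence 4%
(Bernoulli per patient). Each true case independently carries each
criterion signature with a documentation probability — defaults 0.53 (ICD),
0.38 (ATC), 0.91 (laboratory), tracking the marginal fractions observed in
such a register; a case may carry none (≈2.6% of cases), emulating
undocumented disease. Planted fasting-glucose signatures are drawn as
threshold + Lognormal(ln 2, 0.5) mmol/L — median 9.0 mmol/L for plasma and
always above the cut-off, so a planted laboratory signature always
qualifies; non-case fasting glucose is Normal(5.0, 0.5) plasma /
Normal(4.5, 0.4) blood, exceeding the cut-off in well under 0.1% of
entries. Background event intensities (contacts 2.0/patient-year,
diagnoses and prescriptions 0.7, labs 0.9, the rest 0.15–0.4) are ordinary
primary-care utilisation figures chosen once for realism; codes come from
small non-diabetic catalogues, with the ICD version switching with the
calendar in 1997.

A configurable fraction of non-cases (default 0.0012, or an exact quota)
carries an inaccurate oral-antidiabetic prescription;
`inject_soft_deletions` flips its `deleted` flag and soft-deletes contact
entries (default probability 0.004, or a quota). Injection only toggles
flags — entry counts are conserved — and patients, events and deletions use
separate RNG streams spawned from one seed, so toggling deletions never
perturbs the rest of the store. Identical seed and configuration give
byte-identical CSV output.

Two exact fixtures complement the statistical generator:

* `generate_fixture_from_marginals` builds a store whose caseset has
  *exactly* the requested per-criterion counts and union, via a greedy
  cover (largest criterion placed over the uncovered tail first, remainders
  folded onto the head); explicit seven-region Venn counts are honoured
  when given, and infeasible requests (a marginal above the union, or
  marginals that cannot cover it) raise.
* `generate_congruity_fixture` plans register rows per patient so each
  criterion stratum totals an exact item count (defaults 1,060/1,216/769
  across 21 patients each), every patient has rows in all nine tables, and
  a chosen number of contact entries (default 13) are soft-deleted.

What the generator does not emulate: realistic clinical language (narrative
text is templated), within-patient longitudinal correlation of values,
comorbidity structure, coding drift beyond the 1997 ICD switch, or
inter-criterion correlation beyond independent documentation probabilities.
Passing tests therefore demonstrate the correctness of the extraction and
validation machinery under controlled conditions, not the clinical
performance of any criterion set on real records.

## Numerical and design choices

* Rounding: half-up via `decimal`, one decimal percent by default —
  `round_percent(433/445) == 97.3`.
* Glucose threshold boundary: inclusive (a fasting plasma glucose of
  exactly 7.0 mmol/L qualifies); the strict comparator is available per
  rule.
* Stable sorts everywhere ties matter; item ordinals follow source order.
* The brute-force audit loop is row-wise by design (it mirrors a manual
  review and keeps the classification auditable); at the protocol's sample
  sizes (thousands of items) this costs well under a second.
* Problem sizes in the test suite follow the study conditions where stated
  (full population 10,753; audit sample 63 PINs / 3,045 items); randomized
  property checks use many small stores (e.g. 10,000 stores of ≤ 8
  patients for the deletion-mode monotonicity property) because breadth
  over store shapes, not store size, is what exercises those invariants.
* A run's global seed is expanded into per-stage seeds through
  `numpy.random.SeedSequence` spawning, so any stage can be re-run in
  isolation with its own recorded seed.

## Known limitations

* Dates only — the underlying systems sometimes record time intervals of
  contact; intervals are out of scope.
* No free-text case detection: inclusion criteria search structured data
  only, narrative text is extracted but never queried for case finding.
* No de-identification layer; PINs pass through unchanged (synthetic data
  only).
* Confidence intervals for the accuracy metrics are not computed; the
  protocol reports point estimates.
* The Measurement vs Biometrics distinction is kept as in the source
  modules; both are extracted verbatim.
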