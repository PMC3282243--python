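"""Validation protocol: stratified sampling, congruity audit, diagnostic
accuracy, Venn partition, prevalence."""

import numpy as np
import pandas as pd
import pytest

from register_forge import (
    ExtractionSpec,
    InclusionCriteria,
    SamplingPlan,
    compare_items,
    compute_diagnostic_metrics,
    compute_prevalence,
    compute_venn_partition,
    extract_register,
    find_cases,
    generate_congruity_fixture,
    generate_fixture_from_marginals,
    round_percent,
    select_audit_sample,
)


@pytest.fixture(scope="module")
def audit_setting():
    """Store + caseset with exactly seven eligible patients per stratum."""
    db, _ = generate_congruity_fixture(seed=0)
    cs = find_cases(db, InclusionCriteria(deletion_mode="deletion_blind"))
    return db, cs


class TestSelectAuditSample:
    def test_full_sample_has_63_distinct_pins_21_per_criterion(self, audit_setting):
        db, cs = audit_setting
        sample = select_audit_sample(cs, db, SamplingPlan(seed=3))
        assert len(sample) == 63
        assert len(sample.pins) == 63
        for c in ("icd", "atc", "lab"):
            assert len(sample.pins_by_criterion(c)) == 21

    def test_exact_stratum_is_taken_fully_regardless_of_seed(self, audit_setting):
        db, cs = audit_setting
        pins_by_seed = {select_audit_sample(cs, db, SamplingPlan(seed=s)).pins == cs.pins
                        for s in range(5)}
        assert pins_by_seed == {True}

    def test_fixed_seed_is_fully_reproducible(self):
        db, _ = generate_fixture_from_marginals(120, 70, 50, 80, seed=5)
        cs = find_cases(db, InclusionCriteria())
        a = select_audit_sample(cs, db, SamplingPlan(seed=9))
        b = select_audit_sample(cs, db, SamplingPlan(seed=9))
        assert a.selections.equals(b.selections)

    @pytest.mark.parametrize("seed", range(50))
    def test_no_pin_is_ever_selected_twice(self, seed):
        db, _ = generate_fixture_from_marginals(150, 90, 70, 100, seed=1)
        cs = find_cases(db, InclusionCriteria())
        sample = select_audit_sample(cs, db, SamplingPlan(seed=seed))
        assert not sample.selections["pin"].duplicated().any()

    def test_stratum_shortfall_warns_and_logs(self):
        # only one patient qualifies by ICD, so the ICD strata cannot fill
        db, _ = generate_fixture_from_marginals(10, 1, 8, 8, seed=2)
        cs = find_cases(db, InclusionCriteria())
        with pytest.warns(UserWarning, match="short"):
            sample = select_audit_sample(cs, db, SamplingPlan(seed=0))
        assert any("short" in line for line in sample.log)

    def test_pin_assigned_to_period_of_first_qualifying_event(self, audit_setting):
        db, cs = audit_setting
        plan = SamplingPlan(seed=1)
        sample = select_audit_sample(cs, db, plan)
        for _, row in sample.selections.iterrows():
            p0, p1 = plan.periods[row["period_index"]]
            assert pd.Timestamp(p0) <= row["first_event"] <= pd.Timestamp(p1)


class TestCompareItems:
    def test_clean_store_audits_fully_congruent(self, audit_setting):
        db, cs = audit_setting
        # deletion-aware extraction never emits the deleted contacts
        reg = extract_register(db, cs, ExtractionSpec(include_deleted=False))
        sample = select_audit_sample(cs, db, SamplingPlan(seed=0))
        rep = compare_items(reg, db, sample)
        assert rep.n_extraction_only == 0 and rep.n_source_only == 0
        assert rep.congruity_rate == 1.0

    def test_deleted_items_are_extraction_only_then_resolved(self, audit_setting):
        db, cs = audit_setting
        reg = extract_register(db, cs, ExtractionSpec(include_deleted=True))
        sample = select_audit_sample(cs, db, SamplingPlan(seed=0))
        rep = compare_items(reg, db, sample)
        assert rep.n_compared == 3045
        assert rep.n_extraction_only == 13
        assert rep.n_resolved_deleted == 13
        per_table = rep.per_table.set_index("table")
        assert per_table.loc["Contacts", "n_extraction_only"] == 13
        assert all(per_table.loc[t, "n_extraction_only"] == 0
                   for t in per_table.index if t != "Contacts")
        assert round_percent(rep.congruity_rate) == 99.6
        assert rep.post_audit_rate == 1.0

    def test_injected_corruptions_are_counted_exactly(self, audit_setting):
        db, cs = audit_setting
        reg = extract_register(db, cs, ExtractionSpec(include_deleted=False))
        sample = select_audit_sample(cs, db, SamplingPlan(seed=0))
        k = 5
        drugs = reg.tables["Drugs"]
        for i in range(k):
            drugs.loc[drugs.index[i], "dosage"] = "9x9"
        rep = compare_items(reg, db, sample)
        assert rep.n_source_only == k
        assert len(rep.mismatches) == k
        assert all(m["fields"] == ["dosage"] for m in rep.mismatches)

    def test_audit_is_exhaustive_over_sampled_pins(self, audit_setting):
        db, cs = audit_setting
        reg = extract_register(db, cs, ExtractionSpec(include_deleted=True))
        sample = select_audit_sample(cs, db, SamplingPlan(seed=0))
        rep = compare_items(reg, db, sample)
        assert rep.n_compared == reg.n_items(sample.pins)
        assert (rep.n_matched + rep.n_source_only + rep.n_extraction_only
                == rep.n_compared)

    def test_period_restricted_audit_examines_fewer_items(self, audit_setting):
        db, cs = audit_setting
        reg = extract_register(db, cs, ExtractionSpec(include_deleted=True))
        plan = SamplingPlan(seed=0, restrict_to_period=True)
        sample = select_audit_sample(cs, db, plan)
        rep_full = compare_items(reg, db, sample)
        rep_restricted = compare_items(reg, db, sample, plan)
        assert rep_restricted.n_compared <= rep_full.n_compared


class TestDiagnosticMetrics:
    def test_printed_study_counts_reproduce_printed_percentages(self):
        test = {f"p{i}" for i in range(445)}
        ref = {f"p{i}" for i in range(433)}  # reference is a subset of test
        m = compute_diagnostic_metrics(test, ref, 10_753)
        pct = m.as_percent()
        assert pct == {"sensitivity": 100.0, "specificity": 99.9,
                       "ppv": 97.3, "npv": 100.0}

    def test_identical_casesets_are_perfect(self):
        s = {"a", "b", "c"}
        m = compute_diagnostic_metrics(s, s, 10)
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_confusion_matrix_matches_membership_oracle(self, seed):
        rng = np.random.default_rng(seed)
        population = [f"p{i}" for i in range(200)]
        test = {p for p in population if rng.random() < 0.3}
        ref = {p for p in population if rng.random() < 0.3}
        m = compute_diagnostic_metrics(test, ref, 200)
        tp = sum(1 for p in population if p in test and p in ref)
        fp = sum(1 for p in population if p in test and p not in ref)
        fn = sum(1 for p in population if p not in test and p in ref)
        tn = sum(1 for p in population if p not in test and p not in ref)
        assert (m.tp, m.fp, m.fn, m.tn) == (tp, fp, fn, tn)
        assert m.tp + m.fp + m.fn + m.tn == m.n_total

    def test_inconsistent_population_size_rejected(self):
        with pytest.raises(ValueError):
            compute_diagnostic_metrics({"a", "b"}, {"c"}, 2)


class TestVennPartition:
    def test_disjoint_criteria_fill_only_singleton_regions(self):
        db, _ = generate_fixture_from_marginals(3, 1, 1, 1, seed=0)
        part = compute_venn_partition(find_cases(db, InclusionCriteria()))
        assert part.regions["icd_only"] == 1
        assert part.regions["atc_only"] == 1
        assert part.regions["lab_only"] == 1
        assert part.union == 3

    @pytest.mark.parametrize("seed", range(20))
    def test_region_sums_satisfy_inclusion_exclusion(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        flags = pd.DataFrame({
            "by_icd": rng.random(n) < 0.5,
            "by_atc": rng.random(n) < 0.5,
            "by_lab": rng.random(n) < 0.5,
        }, index=[f"p{i}" for i in range(n)])
        flags = flags[flags.any(axis=1)]
        from register_forge import CaseSet
        cs = CaseSet(flags=flags, criteria=InclusionCriteria(), db_fingerprint="x")
        part = compute_venn_partition(cs)
        marg = part.marginals()
        # enumeration oracle
        assert marg["icd"] == int(flags["by_icd"].sum())
        assert marg["atc"] == int(flags["by_atc"].sum())
        assert marg["lab"] == int(flags["by_lab"].sum())
        assert part.union == len(flags)
        # inclusion–exclusion identity over the three marginals
        i, a, l = flags["by_icd"], flags["by_atc"], flags["by_lab"]
        incl_excl = (marg["icd"] + marg["atc"] + marg["lab"]
                     - int((i & a).sum()) - int((i & l).sum()) - int((a & l).sum())
                     + int((i & a & l).sum()))
        assert incl_excl == part.union


class TestPrevalence:
    def test_study_counts_round_to_four_percent(self):
        assert round_percent(compute_prevalence({f"p{i}" for i in range(433)},
                                                10_753)) == 4.0

    def test_empty_caseset_gives_zero(self):
        assert compute_prevalence(set(), 100) == 0.0

    def test_zero_population_is_an_error(self):
        with pytest.raises(ValueError):
            compute_prevalence({"a"}, 0)

    @pytest.mark.parametrize("k,n", [(3, 7), (50, 200), (433, 10753)])
    def test_matches_plain_division(self, k, n):
        assert compute_prevalence({f"p{i}" for i in range(k)}, n) == k / n
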