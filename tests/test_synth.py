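"""Synthetic-store generators: calibration, determinism, deletion injection,
and exact marginal fixtures."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

from register_forge import (
    ConfigurationError,
    InclusionCriteria,
    InfeasibleMarginals,
    SynthConfig,
    add_deleted_rx_noncases,
    find_cases,
    generate_congruity_fixture,
    generate_fixture_from_marginals,
    generate_population,
    inject_soft_deletions,
    validate_database,
    write_database,
)


class TestGeneratePopulation:
    def test_zero_prevalence_plants_no_cases(self):
        _, gt = generate_population(SynthConfig(n_patients=500, prevalence=0.0, seed=1))
        assert gt.n_cases == 0

    def test_zero_patients_yields_empty_valid_store(self):
        db, gt = generate_population(SynthConfig(n_patients=0))
        assert len(db.patients) == 0 and gt.n_cases == 0
        assert validate_database(db) == []

    def test_generated_store_satisfies_all_invariants(self):
        cfg = SynthConfig(n_patients=400, seed=3)
        db, gt = generate_population(cfg)
        db, _ = inject_soft_deletions(db, gt, cfg)
        assert validate_database(db) == []

    def test_same_seed_gives_byte_identical_csv(self, tmp_path):
        for sub in ("a", "b"):
            cfg = SynthConfig(n_patients=150, seed=42)
            db, gt = generate_population(cfg)
            db, _ = inject_soft_deletions(db, gt, cfg)
            write_database(db, tmp_path / sub)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_case_count_within_central_99pct_binomial_interval(self):
        cfg = SynthConfig(seed=5)  # n=10,753, prevalence 4%
        _, gt = generate_population(cfg)
        lo, hi = stats.binom.ppf([0.005, 0.995], cfg.n_patients, cfg.prevalence)
        assert lo <= gt.n_cases <= hi

    def test_documentation_probabilities_recoverable(self):
        """Planted signature fractions among cases track the configured
        documentation probabilities at n = 5,000 within binomial error."""
        cfg = SynthConfig(n_patients=5000, seed=9)
        _, gt = generate_population(cfg)
        cases = gt.table[gt.table["is_case"]]
        for col, p in (("planted_icd", cfg.p_icd_documented),
                       ("planted_atc", cfg.p_atc_documented),
                       ("planted_lab", cfg.p_lab_documented)):
            k, n = int(cases[col].sum()), len(cases)
            lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
            assert lo <= k <= hi, col

    def test_invalid_probability_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(prevalence=1.5)

    def test_noncase_labs_stay_below_diagnostic_threshold(self):
        db, gt = generate_population(SynthConfig(n_patients=2000, seed=13))
        labs = db.labs
        noncase = labs[~labs["pin"].isin(gt.case_pins)
                       & (labs["analyte"] == "glucose") & labs["fasting"]]
        exceed = (noncase["value"] >= 7.0).mean()
        assert exceed < 0.001


class TestInjectSoftDeletions:
    def test_zero_rates_leave_store_unchanged(self):
        cfg = SynthConfig(n_patients=300, seed=2,
                          p_deleted_rx_noncase=0.0, p_deleted_contact=0.0)
        db, gt = generate_population(cfg)
        db2, _ = inject_soft_deletions(db, gt, cfg)
        assert db.equals(db2)

    def test_entry_counts_are_conserved(self):
        cfg = SynthConfig(n_patients=300, seed=2, p_deleted_contact=0.05,
                          n_deleted_rx_noncase=5)
        db, gt = generate_population(cfg)
        db2, _ = inject_soft_deletions(db, gt, cfg)
        assert db.n_entries() == db2.n_entries()

    def test_quota_forces_exact_deletion_blind_excess(self):
        """Exactly 12 quota-deleted prescriptions on non-cases make the
        deletion-blind caseset 12 larger than the deletion-aware one."""
        cfg = SynthConfig(n_patients=1500, seed=4, n_deleted_rx_noncase=12,
                          p_deleted_contact=0.0)
        db, gt = generate_population(cfg)
        db, gt = inject_soft_deletions(db, gt, cfg)
        criteria = InclusionCriteria()
        blind = find_cases(db, criteria.with_mode("deletion_blind"))
        aware = find_cases(db, criteria.with_mode("deletion_aware"))
        assert len(blind) - len(aware) == 12

    def test_only_flags_are_toggled(self):
        cfg = SynthConfig(n_patients=200, seed=6, p_deleted_contact=0.1)
        db, gt = generate_population(cfg)
        db2, _ = inject_soft_deletions(db, gt, cfg)
        a = db.modules["contacts"].drop(columns="deleted")
        b = db2.modules["contacts"].drop(columns="deleted")
        assert a.equals(b)


class TestMarginalsFixture:
    @pytest.mark.parametrize("total,n_icd,n_atc,n_lab", [
        (445, 234, 169, 405),
        (433, 231, 161, 404),
        (3, 1, 1, 1),
        (10, 10, 10, 10),
        (7, 5, 4, 3),
    ])
    def test_requested_marginals_are_achieved_exactly(self, total, n_icd, n_atc, n_lab):
        db, _ = generate_fixture_from_marginals(total, n_icd, n_atc, n_lab, seed=1)
        cs = find_cases(db, InclusionCriteria())
        assert cs.counts() == {"total": total, "icd": n_icd, "atc": n_atc, "lab": n_lab}

    def test_disjoint_singletons_each_flag_one_criterion(self):
        db, _ = generate_fixture_from_marginals(3, 1, 1, 1, seed=0)
        cs = find_cases(db, InclusionCriteria())
        assert (cs.flags.sum(axis=1) == 1).all()

    def test_random_feasible_marginals_round_trip(self):
        rng = np.random.default_rng(20)
        for _ in range(25):
            total = int(rng.integers(1, 60))
            n = sorted(int(rng.integers(0, total + 1)) for _ in range(3))
            if sum(n) < total:
                continue
            db, _ = generate_fixture_from_marginals(total, n[2], n[1], n[0],
                                                    seed=int(rng.integers(2**31)))
            cs = find_cases(db, InclusionCriteria())
            assert cs.counts() == {"total": total, "icd": n[2], "atc": n[1], "lab": n[0]}

    @given(total=st.integers(1, 25), n_icd=st.integers(0, 25),
           n_atc=st.integers(0, 25), n_lab=st.integers(0, 25),
           seed=st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_any_feasible_marginals_are_exact(self, total, n_icd, n_atc, n_lab, seed):
        assume(max(n_icd, n_atc, n_lab) <= total <= n_icd + n_atc + n_lab)
        db, _ = generate_fixture_from_marginals(total, n_icd, n_atc, n_lab, seed=seed)
        cs = find_cases(db, InclusionCriteria())
        assert cs.counts() == {"total": total, "icd": n_icd, "atc": n_atc,
                               "lab": n_lab}

    @pytest.mark.parametrize("args", [
        (5, 6, 0, 0),   # marginal exceeds union
        (10, 3, 3, 3),  # cannot cover union
        (3, -1, 2, 2),  # negative marginal
    ])
    def test_infeasible_marginals_raise(self, args):
        with pytest.raises(InfeasibleMarginals):
            generate_fixture_from_marginals(*args)

    def test_explicit_region_counts_are_honoured(self):
        regions = (2, 1, 3, 1, 0, 2, 1)  # icd_only..all_three, total 10
        db, _ = generate_fixture_from_marginals(10, 4, 5, 6,
                                                region_counts=regions, seed=2)
        from register_forge import compute_venn_partition
        part = compute_venn_partition(find_cases(db, InclusionCriteria()))
        assert tuple(part.regions.values()) == regions

    def test_inconsistent_region_counts_raise(self):
        with pytest.raises(InfeasibleMarginals):
            generate_fixture_from_marginals(10, 4, 5, 6,
                                            region_counts=(2, 1, 3, 1, 0, 2, 0))

    def test_fixture_passes_validation(self):
        db, _ = generate_fixture_from_marginals(50, 30, 20, 40, seed=3)
        assert validate_database(db) == []


class TestDeletedRxNoncases:
    def test_appended_patients_only_match_when_deletion_blind(self):
        db, gt = generate_fixture_from_marginals(20, 10, 10, 10, seed=1)
        db, gt = add_deleted_rx_noncases(db, gt, 5, seed=2)
        criteria = InclusionCriteria()
        blind = find_cases(db, criteria.with_mode("deletion_blind"))
        aware = find_cases(db, criteria.with_mode("deletion_aware"))
        assert len(blind) == 25 and len(aware) == 20
        assert validate_database(db) == []


class TestCongruityFixture:
    def test_item_totals_and_strata_are_exact(self):
        db, gt = generate_congruity_fixture(seed=0)
        assert validate_database(db) == []
        assert len(db.patients) == 63
        # per-pin rows across all modules total the planned item counts
        total_rows = sum(len(db.modules[m]) for m in db.modules)
        assert total_rows == 3045
        assert int(db.contacts["deleted"].sum()) == 13

    def test_custom_quota_rejected_when_larger_than_contacts(self):
        with pytest.raises(ConfigurationError):
            generate_congruity_fixture(
                items_per_stratum={"icd": 190, "atc": 190, "lab": 190},
                n_deleted_contacts=100)
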