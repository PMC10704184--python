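"""Evaluation statistics: scaled difference, Mann-Whitney, Holm, trial ensembles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stratseq import (
    PatientRecord,
    compare_ensembles,
    compare_samplers,
    default_scheme,
    holm_bonferroni,
    mann_whitney_one_tailed,
    prevalence_summary,
    run_trials,
    scaled_difference,
    scaled_differences,
)
from stratseq.evaluation import (
    DegenerateCategoryError,
    DegeneracyWarning,
    TrialEnsemble,
)
from stratseq.reporting import format_p_value, histogram_report
from stratseq.synthetic import generate_cohort, table1_spec


class TestScaledDifference:
    @pytest.mark.parametrize(
        "f, n_total, n_open, expected",
        [
            (0.8, 500, 390, 0.025),  # |400 - 390| / 400
            (0.8, 500, 400, 0.0),
            (0.8, 10, 0, 1.0),  # |8 - 0| / 8
            (0.5, 7, 2, abs(3.5 - 2) / 3.5),
        ],
    )
    def test_direct_evaluation(self, f, n_total, n_open, expected):
        assert scaled_difference(f, n_total, n_open) == pytest.approx(expected)

    def test_empty_subcategory_is_undefined(self):
        with pytest.raises(DegenerateCategoryError):
            scaled_difference(0.8, 0, 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            scaled_difference(1.0, 10, 5)
        with pytest.raises(ValueError):
            scaled_difference(0.8, 10, 11)

    @given(n_total=st.integers(1, 400), n_open=st.integers(0, 400),
           f10=st.integers(1, 9))
    def test_symmetric_about_expectation(self, n_total, n_open, f10):
        # d is invariant under reflection N_Open -> 2 f N_T - N_Open.
        f = f10 / 10
        n_open = min(n_open, n_total)
        mirrored = 2 * f * n_total - n_open
        if 0 <= mirrored <= n_total and mirrored == int(mirrored):
            assert scaled_difference(f, n_total, n_open) == pytest.approx(
                scaled_difference(f, n_total, int(mirrored))
            )


def mw_oracle_less(x, y):
    """Independent enumeration oracle: U by pairwise comparison, p by full permutation."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def ustat(idx_x):
        idx_x = set(idx_x)
        xs = [pooled[i] for i in idx_x]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx_x]
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)

    u_obs = ustat(range(n1))
    us = [ustat(c) for c in itertools.combinations(range(len(pooled)), n1)]
    return u_obs, sum(u <= u_obs + 1e-9 for u in us) / len(us)


class TestMannWhitney:
    def test_complete_separation_small_sample(self):
        u, p = mann_whitney_one_tailed([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 6)  # one of C(4,2)=6 rank assignments

    def test_identical_multisets_give_no_evidence(self):
        _, p = mann_whitney_one_tailed([1, 2, 3], [1, 2, 3])
        assert p >= 0.5

    def test_all_values_tied_is_degenerate(self):
        with pytest.warns(DegeneracyWarning):
            _, p = mann_whitney_one_tailed([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=6).astype(float)  # ties likely
        y = rng.integers(0, 5, size=7).astype(float)
        if np.ptp(np.concatenate([x, y])) == 0:
            pytest.skip("degenerate draw")
        u_oracle, p_oracle = mw_oracle_less(x, y)
        u, p = mann_whitney_one_tailed(x, y)
        assert u == pytest.approx(u_oracle)
        assert p == pytest.approx(p_oracle)

    @pytest.mark.parametrize("seed", range(8))
    def test_asymptotic_path_agrees_with_exact_within_001(self, seed):
        # Continuous data, 10 per arm: normal approximation with continuity
        # correction tracks the exact permutation p-value closely.
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(0.3, size=10)
        _, p_exact = mann_whitney_one_tailed(x, y)  # enumeration path
        _, p_approx = mann_whitney_one_tailed(x, y, exact_threshold=0)
        assert abs(p_exact - p_approx) < 0.01


class TestHolmBonferroni:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ((0.001, 0.02, 0.04), [True, True, True]),  # 0.05/3, 0.05/2, 0.05/1
            ((0.04, 0.04), [False, False]),  # first tested at 0.025, step-down stops
            ((0.049,), [True]),
        ],
    )
    def test_hand_computed_examples(self, pvals, expected):
        assert list(holm_bonferroni(pvals, alpha=0.05)) == expected

    def test_flags_preserve_input_order(self):
        flags = holm_bonferroni([0.9, 0.0001, 0.5], alpha=0.05)
        assert list(flags) == [False, True, False]

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_monotone_in_p(self, pvals):
        flags = holm_bonferroni(pvals, alpha=0.05)
        for i, j in itertools.permutations(range(len(pvals)), 2):
            if pvals[i] < pvals[j] and flags[j]:
                assert flags[i]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.5])


def one_stratum_batch(n, sex="Female"):
    return [
        PatientRecord(patient_id=f"P{i}", age_years=50.0, race="White",
                      sex_at_birth=sex, ethnicity="Not Hispanic or Latino",
                      covid_status="No", modalities=frozenset({"CR"}))
        for i in range(n)
    ]


class TestRunTrials:
    def test_master_seed_reproducibility(self, scheme):
        batch = generate_cohort(table1_spec(n_patients=150), seed=1)
        e1 = run_trials(batch, scheme, "stratified", 20, master_seed=5)
        e2 = run_trials(batch, scheme, "stratified", 20, master_seed=5)
        assert np.array_equal(e1.open_counts, e2.open_counts)
        e3 = run_trials(batch, scheme, "stratified", 20, master_seed=6)
        assert not np.array_equal(e1.open_counts, e3.open_counts)

    def test_counts_partition_input(self, scheme):
        batch = generate_cohort(table1_spec(n_patients=150), seed=2)
        ens = run_trials(batch, scheme, "naive", 15, master_seed=0)
        assert np.all(ens.open_counts + ens.sequestered_counts
                      == ens.input_counts[None, :])

    def test_one_stratum_batch_respects_count_contract(self, scheme):
        ens = run_trials(one_stratum_batch(10), scheme, "stratified", 25,
                         master_seed=3)
        assert np.all(ens.open_totals == 8)  # 0.8*10 integral
        j = ens.column("sex_at_birth", "Female")
        assert np.all(ens.open_counts[:, j] == 8)

    def test_samplers_draw_independent_streams(self, scheme):
        batch = generate_cohort(table1_spec(n_patients=150), seed=3)
        es = run_trials(batch, scheme, "stratified", 10, master_seed=9)
        en = run_trials(batch, scheme, "naive", 10, master_seed=9)
        assert not np.array_equal(es.open_counts, en.open_counts)


class TestPrevalenceSummary:
    def test_single_trial_prevalence_is_simple_ratio(self, scheme):
        subcats = (("sex_at_birth", "Female"),)
        ens = TrialEnsemble(
            sampler="stratified", n_trials=1, open_fraction=0.8, n_patients=10,
            master_seed=0, subcategories=subcats,
            input_counts=np.array([5]),
            open_counts=np.array([[4]]),  # 4 of the 8 open patients are Female
            open_totals=np.array([8]),
        )
        df = prevalence_summary(ens)
        assert df.loc[0, "open_mean_pct"] == pytest.approx(50.0)
        assert df.loc[0, "open_sd_pct"] == 0.0
        assert df.loc[0, "sequestered_mean_pct"] == pytest.approx(50.0)  # 1 of 2

    def test_deterministic_ensemble_has_zero_sd(self, scheme):
        # 5 identical patients in one stratum: 4 go open in every trial.
        ens = run_trials(one_stratum_batch(5), scheme, "stratified", 30,
                         master_seed=1)
        df = prevalence_summary(ens)
        female = df[(df.variable == "sex_at_birth") & (df.subcategory == "Female")]
        assert float(female["open_mean_pct"].iloc[0]) == 100.0
        assert float(female["open_sd_pct"].iloc[0]) == 0.0

    def test_mean_open_prevalence_recovers_input(self, stratified_ensemble_2000):
        # Unbiasedness: mean open prevalence within 3 Monte-Carlo standard
        # errors of the input prevalence for every well-populated subcategory.
        df = prevalence_summary(stratified_ensemble_2000)
        well = df[df.input_count >= 50]
        se = well.open_sd_pct / math.sqrt(stratified_ensemble_2000.n_trials)
        assert (abs(well.open_mean_pct - well.input_prevalence_pct) <= 3 * se).all()


class TestCompareSamplers:
    def test_degenerate_comparison_flags_p_of_one(self, scheme):
        # One stratum of 5 identical patients: both samplers always send
        # exactly 4 open, every scaled difference is identical.
        with pytest.warns(DegeneracyWarning):
            report = compare_samplers(one_stratum_batch(5), scheme,
                                      n_trials=12, master_seed=0)
        row = report.table[(report.table.variable == "sex_at_birth")
                           & (report.table.subcategory == "Female")]
        assert float(row["p_value"].iloc[0]) == 1.0

    def test_single_category_variable_shows_no_advantage(self, scheme):
        # All patients female: the Female count equals the arm total for both
        # samplers, whose totals follow the identical global count rule.
        batch = [
            PatientRecord(patient_id=f"Q{i}", age_years=float(20 + (i * 7) % 60),
                          race="White", sex_at_birth="Female",
                          ethnicity="Not Hispanic or Latino", covid_status="No",
                          modalities=frozenset({"CR"}))
            for i in range(37)
        ]
        report = compare_samplers(batch, scheme, n_trials=40, master_seed=2)
        row = report.table[(report.table.variable == "sex_at_birth")
                           & (report.table.subcategory == "Female")]
        assert float(row["p_value"].iloc[0]) >= 0.05

    def test_scaled_differences_nan_only_for_empty_subcategories(
        self, scheme, stratified_ensemble_2000
    ):
        d = scaled_differences(stratified_ensemble_2000)
        empty = stratified_ensemble_2000.input_counts == 0
        assert np.all(np.isnan(d[:, empty]))
        assert not np.any(np.isnan(d[:, ~empty]))

    def test_sequestered_arm_uses_complementary_expectation(self, scheme):
        ens = run_trials(one_stratum_batch(10), scheme, "stratified", 5,
                         master_seed=4)
        j = ens.column("sex_at_birth", "Female")
        d = scaled_differences(ens, arm="sequestered")
        assert np.all(d[:, j] < 1e-12)  # always exactly 2 of 10 sequestered


class TestReportingHelpers:
    def test_p_value_formatting(self):
        assert format_p_value(float("nan")) == "N/A"
        assert format_p_value(0.0004, True) == "p < 0.01 **"
        assert format_p_value(0.7) == "p = 0.70"

    def test_histogram_report_smoke(self, scheme, tmp_path):
        batch = generate_cohort(table1_spec(n_patients=200), seed=6)
        es = run_trials(batch, scheme, "stratified", 30, master_seed=0)
        en = run_trials(batch, scheme, "naive", 30, master_seed=0)
        path = histogram_report((es, en), "race", tmp_path)
        assert path.exists() and path.stat().st_size > 0

    def test_histogram_report_degenerate_ensemble(self, scheme, tmp_path):
        es = run_trials(one_stratum_batch(5), scheme, "stratified", 10, master_seed=0)
        en = run_trials(one_stratum_batch(5), scheme, "naive", 10, master_seed=0)
        path = histogram_report((es, en), "sex_at_birth", tmp_path)
        assert path.exists()
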