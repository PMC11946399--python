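"""Reliability surface: normality gating, paired tests, ICC, SEM/MDC,
subgroup comparison, and the assembled per-index table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gaitrel as g
from gaitrel.reliability import (
    ReliabilityConfig,
    agreement_frame,
    cohens_d,
    descriptives_frame,
    icc_3_1,
    mdc,
    normality_test,
    paired_comparison,
    reliability_table,
    sem,
    subgroup_compare,
)
from gaitrel.synthetic import generate_paired_values
from gaitrel.types import INDEX_NAMES


def _brute_force_icc(x, y, form):
    """Independent oracle: explicit two-way mean-squares arithmetic."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    ss_rows = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((v - grand) ** 2 for v in data.ravel())
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if form == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestNormality:
    def test_null_acceptance_rate(self):
        """Standard-normal samples (n = 49) pass Shapiro–Wilk ≥ 95 % of runs."""
        rng = np.random.default_rng(0)
        passed = sum(
            normality_test(rng.normal(size=49))[2] for _ in range(400)
        )
        assert passed / 400 >= 0.93  # nominal 95 % minus binomial noise

    def test_exponential_power(self):
        """Strongly skewed (exponential) samples are rejected ≥ 90 % of runs."""
        rng = np.random.default_rng(1)
        rejected = sum(
            not normality_test(rng.exponential(size=49))[2] for _ in range(300)
        )
        assert rejected / 300 >= 0.90

    def test_constant_vector_degenerate(self):
        stat, p, ok = normality_test(np.full(10, 1.5))
        assert np.isnan(stat) and np.isnan(p) and not ok


class TestPairedComparison:
    def test_identical_sessions_degenerate_convention(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p, d, d_ci, used, _ = paired_comparison(x, x)
        assert p == 1.0 and d == 0.0 and used == "degenerate"

    def test_constant_shift_gives_large_effect(self, rng):
        x = rng.normal(10, 1, 30)
        y = x + 2.0 + rng.normal(0, 0.1, 30)
        p, d, _, used, _ = paired_comparison(x, y)
        assert d > 0.8  # large-effect band
        assert p < 1e-6

    def test_toy_table_matches_textbook_arithmetic(self):
        """5-pair worked example against the direct t-statistic formula."""
        x = np.array([10.0, 12.0, 9.0, 11.0, 13.0])
        y = np.array([11.2, 13.1, 9.4, 12.3, 14.9])
        diff = y - x
        t_stat = diff.mean() / (diff.std(ddof=1) / np.sqrt(5))
        p_expected = 2 * stats.t.sf(abs(t_stat), df=4)
        p, d, _, used, normal = paired_comparison(x, y)
        assert used == "t" and normal
        assert p == pytest.approx(p_expected, rel=1e-12)
        assert d == pytest.approx(diff.mean() / diff.std(ddof=1), rel=1e-12)

    def test_skewed_differences_route_to_wilcoxon(self, rng):
        x = rng.normal(10, 1, 40)
        y = x + rng.exponential(2.0, 40) ** 2
        _, _, _, used, normal = paired_comparison(x, y)
        assert used == "wilcoxon" and not normal


class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        for form in ("consistency", "absolute_agreement"):
            est, ci = icc_3_1(x, x, form)
            assert est == 1.0 and ci == (1.0, 1.0)

    @pytest.mark.parametrize("form", ["consistency", "absolute_agreement"])
    def test_toy_table_matches_brute_force_oracle(self, form):
        x = np.array([9.0, 10.5, 12.0, 8.0, 11.0, 10.0])
        y = np.array([9.4, 10.2, 12.5, 8.3, 10.6, 9.7])
        est, ci = icc_3_1(x, y, form)
        assert est == pytest.approx(_brute_force_icc(x, y, form), abs=1e-10)
        assert ci[0] <= est <= ci[1]

    @pytest.mark.parametrize("form, pg_type", [("consistency", "ICC(C,1)"), ("absolute_agreement", "ICC(A,1)")])
    def test_matches_pingouin(self, rng, form, pg_type):
        """Cross-check estimate and CI against an independent implementation."""
        pg = pytest.importorskip("pingouin")
        x = rng.normal(10, 2, 15)
        y = x + rng.normal(0.2, 0.9, 15)
        est, ci = icc_3_1(x, y, form)
        df = pd.DataFrame({
            "s": list(range(15)) * 2,
            "r": ["a"] * 15 + ["b"] * 15,
            "v": np.r_[x, y],
        })
        res = pg.intraclass_corr(df, targets="s", raters="r", ratings="v").set_index("Type")
        assert est == pytest.approx(res.loc[pg_type, "ICC"], abs=1e-10)
        np.testing.assert_allclose(ci, res.loc[pg_type, "CI95"], atol=0.011)

    def test_independent_sessions_center_on_zero(self):
        rng = np.random.default_rng(5)
        estimates = [
            icc_3_1(rng.normal(size=200), rng.normal(size=200))[0] for _ in range(300)
        ]
        assert abs(np.mean(estimates)) < 0.05

    def test_zero_between_subject_variance_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            icc_3_1(np.full(5, 2.0), np.full(5, 2.0))

    def test_noisier_retest_lowers_icc_in_expectation(self):
        """Adding independent noise to the retest never helps reliability."""
        rng = np.random.default_rng(9)
        base, noisy = [], []
        for _ in range(200):
            x, y = generate_paired_values(49, 0.8, rng=rng)
            base.append(icc_3_1(x, y)[0])
            noisy.append(icc_3_1(x, y + rng.normal(0, 0.8, 49))[0])
        assert np.mean(noisy) < np.mean(base)


class TestSemMdc:
    @pytest.mark.parametrize(
        "sd, icc, expected", [(10.0, 0.84, 4.0), (7.0, 1.0, 0.0), (7.0, 0.0, 7.0)]
    )
    def test_sem_formula(self, sd, icc, expected):
        assert sem(sd, icc) == pytest.approx(expected)

    def test_sem_rejects_icc_above_one(self):
        with pytest.raises(ValueError):
            sem(1.0, 1.2)

    def test_mdc_conventions(self):
        assert mdc(0.64, "printed_2") == pytest.approx(2.51, abs=0.005)
        assert mdc(1.0, "sqrt2") == pytest.approx(2.7719, abs=1e-4)
        assert mdc(0.0, "printed_2") == 0.0


class TestSubgroup:
    def test_exact_separated_groups(self):
        """(1,2,3) vs (4,5,6): U = 0 and exact two-sided p = 0.1."""
        u, p = subgroup_compare(
            np.array([1.0, 2, 3, 4, 5, 6]), np.array(["a", "a", "a", "b", "b", "b"])
        )
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_type_i_error_rate(self):
        rng = np.random.default_rng(2)
        groups = np.array(["a"] * 200 + ["b"] * 200)
        rejections = sum(
            subgroup_compare(rng.normal(size=400), groups)[1] < 0.05
            for _ in range(300)
        )
        assert 0.02 <= rejections / 300 <= 0.08

    def test_power_under_location_shift(self):
        rng = np.random.default_rng(3)
        groups = np.array(["a"] * 50 + ["b"] * 50)
        hits = sum(
            subgroup_compare(
                np.r_[rng.normal(size=50), rng.normal(1.0, 1.0, 50)], groups
            )[1] < 0.05
            for _ in range(200)
        )
        assert hits / 200 > 0.80

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            subgroup_compare(np.array([1.0, 2.0]), np.array(["a", "a"]))


def _index_frames(n=8, seed=0, icc=0.9):
    rng = np.random.default_rng(seed)
    rows_t, rows_r = [], []
    for i in range(n):
        rows_t.append({"subject_id": f"s{i:02d}"})
        rows_r.append({"subject_id": f"s{i:02d}"})
    tdf, rdf = pd.DataFrame(rows_t), pd.DataFrame(rows_r)
    for name in INDEX_NAMES:
        x, y = generate_paired_values(n, icc, mean=5.0, sd=1.0, rng=rng)
        tdf[name] = x
        rdf[name] = y
    return tdf, rdf


class TestReliabilityTable:
    def test_shape_and_chain_consistency(self):
        tdf, rdf = _index_frames()
        records = reliability_table(tdf, rdf)
        assert len(records) == 15
        for r in records:
            assert r.mdc == pytest.approx(r.sem * 1.96 * r.mdc_multiplier, rel=1e-12)
            assert r.icc_ci[0] <= r.icc <= r.icc_ci[1]
            assert r.sem_ci[0] <= r.sem <= r.sem_ci[1]
            assert r.sem >= 0 and r.mdc >= 0
        assert len(descriptives_frame(records)) == 15
        assert len(agreement_frame(records)) == 15

    def test_identical_sessions_propagate_perfect_agreement(self):
        tdf, _ = _index_frames()
        records = reliability_table(tdf, tdf.copy())
        for r in records:
            assert r.icc == 1.0
            assert r.sem == 0.0 and r.mdc == 0.0

    def test_row_order_is_irrelevant(self):
        tdf, rdf = _index_frames()
        shuffled = rdf.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = agreement_frame(reliability_table(tdf, rdf))
        b = agreement_frame(reliability_table(tdf, shuffled))
        pd.testing.assert_frame_equal(a, b)

    def test_unmatched_subjects_rejected(self):
        tdf, rdf = _index_frames()
        with pytest.raises(ValueError, match="s00"):
            reliability_table(tdf, rdf[rdf["subject_id"] != "s00"])

    def test_mdc_convention_switch(self):
        tdf, rdf = _index_frames()
        printed = reliability_table(tdf, rdf, ReliabilityConfig(mdc_convention="printed_2"))
        root2 = reliability_table(tdf, rdf, ReliabilityConfig(mdc_convention="sqrt2"))
        for a, b in zip(printed, root2):
            assert b.mdc == pytest.approx(a.mdc * np.sqrt(2) / 2, rel=1e-12)


class TestParameterRecovery:
    @pytest.mark.parametrize("true_icc", [0.6, 0.8, 0.95])
    def test_ci_coverage_at_study_size(self, true_icc):
        """95 % CIs cover the true ICC in ≥ 90 % of simulated cohorts."""
        rng = np.random.default_rng(42)
        covered = 0
        reps = 200
        for _ in range(reps):
            x, y = generate_paired_values(49, true_icc, rng=rng)
            _, (lo, hi) = icc_3_1(x, y)
            covered += lo <= true_icc <= hi
        assert covered / reps >= 0.90
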