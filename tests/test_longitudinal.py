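import math

import numpy as np
import pandas as pd
import pytest

from fscshape.longitudinal import (
    DesignError,
    friedman_adjusted,
    indicator_comparison,
    read_cohort_csv,
    spearman,
    standard_error_of_measurement,
    validate_cohort_table,
    variance_components,
    write_cohort_csv,
)
from fscshape.shape_stats import ShapeIndicators, SphIDecomposition
from fscshape.synthetic_data import CohortSpec, simulate_cohort

from .oracles import (
    friedman_permutation_pvalue,
    friedman_statistic_oracle,
    ml_variance_components_oracle,
    spearman_oracle,
)


def _fake_indicators(sphi, pcd, kurt):
    return ShapeIndicators(
        kurtosis_excess=kurt, pcd=pcd, sphi=sphi, estimator="G2",
        decomposition=SphIDecomposition(bimodal=sphi is not None), n_events=1000,
    )


class TestVarianceComponents:
    def test_matches_balanced_ml_closed_form(self):
        table = simulate_cohort(CohortSpec(mu=2.19, sigma_between=0.3,
                                           sigma_within=0.1, seed=21))
        vc = variance_components(table)
        grouped = [g["value"].tolist() for _, g in table.groupby("subject")]
        mu, vb, vw = ml_variance_components_oracle(grouped)
        assert vc.mean == pytest.approx(mu, rel=1e-4)
        assert vc.sd_between == pytest.approx(math.sqrt(vb), rel=0.02)
        assert vc.sd_within == pytest.approx(math.sqrt(vw), rel=0.02)

    def test_sem_invariant_holds_exactly(self):
        for seed in range(5):
            table = simulate_cohort(CohortSpec(sigma_between=0.25,
                                               sigma_within=0.08, seed=seed))
            vc = variance_components(table)
            assert vc.sem == standard_error_of_measurement(vc.sd_within, vc.n_subjects)

    def test_zero_within_noise(self):
        table = simulate_cohort(CohortSpec(sigma_between=0.3, sigma_within=0.0,
                                           seed=22))
        vc = variance_components(table)
        assert vc.sd_within == pytest.approx(0.0, abs=1e-4)
        assert vc.r_ratio == pytest.approx(0.0, abs=1e-6)

    def test_singular_between_fit_flags_infinite_ratio(self):
        table = simulate_cohort(CohortSpec(sigma_between=0.0, sigma_within=0.1,
                                           seed=23))
        vc = variance_components(table)
        assert vc.r_ratio == math.inf or vc.r_ratio > 50

    def test_sd_ratio_scale(self):
        table = simulate_cohort(CohortSpec(sigma_between=0.3, sigma_within=0.1,
                                           seed=24))
        var_scale = variance_components(table, ratio_scale="variance")
        sd_scale = variance_components(table, ratio_scale="sd")
        assert sd_scale.r_ratio == pytest.approx(math.sqrt(var_scale.r_ratio), rel=1e-9)

    def test_unbalanced_design_accepted(self):
        table = simulate_cohort(CohortSpec(sigma_between=0.3, sigma_within=0.1,
                                           seed=25))
        table = table.drop(table.index[0])  # one subject loses one visit
        vc = variance_components(table)
        assert vc.n_subjects == 10 and vc.sd_between > 0

    def test_design_errors(self):
        with pytest.raises(DesignError):
            validate_cohort_table(pd.DataFrame({"subject": ["a"], "value": [1.0]}))
        dup = pd.DataFrame({"subject": ["a", "a", "b", "b"],
                            "time_point": ["t1", "t1", "t1", "t2"],
                            "value": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(DesignError, match="duplicate"):
            validate_cohort_table(dup)
        single = pd.DataFrame({"subject": ["a", "b"], "time_point": ["t1", "t1"],
                               "value": [1.0, 2.0]})
        with pytest.raises(DesignError):
            validate_cohort_table(single)

    def test_cohort_csv_round_trip(self, tmp_path):
        table = simulate_cohort(CohortSpec(seed=26))
        path = tmp_path / "cohort.csv"
        write_cohort_csv(table, path)
        back = read_cohort_csv(path)
        assert np.allclose(back["value"], table["value"])


class TestSEM:
    def test_formula(self):
        assert standard_error_of_measurement(0.12, 10) == pytest.approx(0.12 / math.sqrt(10))


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0
        rho, _ = spearman([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == -1.0

    def test_ties_against_rank_oracle(self):
        x, y = [1, 2, 3, 4, 5], [5, 6, 7, 8, 7]
        rho, p = spearman(x, y)
        assert rho == pytest.approx(spearman_oracle(x, y), rel=1e-12)
        assert 0 < p < 1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])

    def test_length_checks(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestFriedman:
    def test_identical_columns_null(self):
        m = np.tile(np.arange(6, dtype=float)[:, None], (1, 4))
        res = friedman_adjusted(m)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9
        assert all(p == 1.0 for _, p in res.pairwise)

    def test_monotone_shift_is_significant(self):
        rng = np.random.default_rng(27)
        base = rng.normal(0, 0.2, size=(10, 1))
        shift = np.linspace(0, 1.2, 5)[None, :]
        m = base + shift + rng.normal(0, 0.1, size=(10, 5))
        res = friedman_adjusted(m)
        assert res.p_value < 0.05
        # the extreme condition pair must survive adjustment
        assert dict(res.pairwise)[(0, 4)] < 0.05

    def test_statistic_matches_rank_oracle(self):
        rng = np.random.default_rng(28)
        m = rng.normal(size=(8, 4))
        res = friedman_adjusted(m)
        assert res.chi2 == pytest.approx(friedman_statistic_oracle(m.tolist()), rel=1e-9)

    def test_two_conditions_reduce_to_sign_test(self):
        rng = np.random.default_rng(29)
        m = rng.normal(size=(12, 2))
        res = friedman_adjusted(m)
        d = np.sign(m[:, 0] - m[:, 1])
        expected_chi2 = (d.sum()) ** 2 / len(d)
        assert res.chi2 == pytest.approx(expected_chi2, rel=1e-9)

    def test_small_design_against_exhaustive_permutation(self):
        # 4 subjects × 3 conditions: (3!)^4 = 1296 permutations enumerable.
        clear = [[1.0, 2.0, 3.0], [1.1, 2.2, 3.1], [0.9, 2.1, 3.2], [1.2, 1.9, 2.9]]
        null = [[1.0, 2.0, 3.0], [3.1, 1.1, 2.2], [2.1, 3.2, 0.9], [1.9, 1.2, 2.9]]
        for m, expect_small in ((clear, True), (null, False)):
            res = friedman_adjusted(np.array(m))
            assert res.chi2 == pytest.approx(friedman_statistic_oracle(m), rel=1e-9)
            p_exact = friedman_permutation_pvalue(m)
            assert (p_exact < 0.05) == expect_small
            assert (res.p_value < 0.05) == expect_small

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(DesignError):
            friedman_adjusted(m)

    def test_holm_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(30)
        m = rng.normal(size=(9, 4)) + np.linspace(0, 0.8, 4)[None, :]
        bon = dict(friedman_adjusted(m, adjust="bonferroni").pairwise)
        holm = dict(friedman_adjusted(m, adjust="holm").pairwise)
        assert all(holm[k] <= bon[k] + 1e-12 for k in bon)


class TestIndicatorComparison:
    def test_separation_sweep_sign_pattern(self):
        # stronger bimodality: SphI up, kurtosis down, PCD drifting up
        samples = [
            _fake_indicators(sphi=1.0 + 0.1 * i, pcd=-0.4 + 0.02 * i + 0.001 * (-1) ** i,
                             kurt=-0.2 - 0.1 * i)
            for i in range(12)
        ]
        matrix = indicator_comparison(samples)
        assert matrix.loc["kurtosis", "sphi"] < -0.9
        assert matrix.loc["kurtosis", "pcd"] < 0
        assert matrix.loc["sphi", "pcd"] > 0

    def test_matrix_symmetry_and_diagonal(self):
        rng = np.random.default_rng(31)
        samples = [_fake_indicators(*rng.normal(size=3)) for _ in range(10)]
        matrix = indicator_comparison(samples)
        assert np.allclose(matrix.values, matrix.values.T)
        assert np.allclose(np.diag(matrix.values), 1.0)
        assert list(matrix.columns) == ["sphi", "pcd", "kurtosis"]
        assert matrix.attrs["p_values"].shape == (3, 3)

    def test_undefined_sphi_samples_are_dropped(self):
        samples = [_fake_indicators(None, 0.1, -0.5)] + [
            _fake_indicators(1.0 + i, 0.1 * i, -0.1 * i) for i in range(5)
        ]
        matrix = indicator_comparison(samples)
        assert matrix.shape == (3, 3)

    def test_identical_samples_rejected(self):
        samples = [_fake_indicators(2.0, -0.3, -0.8)] * 5
        with pytest.raises(ValueError):
            indicator_comparison(samples)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            indicator_comparison([_fake_indicators(2.0, -0.3, -0.8)] * 2)
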