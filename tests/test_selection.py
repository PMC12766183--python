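import numpy as np
import pandas as pd
import pytest

from _oracles import lasso_cox_1d_grid
from proteorisk.models import fit_cox
from proteorisk.selection import (SelectionConfig, SelectionResult,
                                  bootstrap_stability, cv_select_lambda,
                                  fit_lasso_cox, run_sex_specific_selection)
from proteorisk.simulate import CohortTable, SimConfig, generate_cohort


def _survival(rng, n, beta):
    X = rng.standard_normal((n, len(beta)))
    t = rng.exponential(np.exp(-(X @ np.asarray(beta))) * 8.0)
    c = rng.exponential(12.0, n)
    time = np.minimum(np.minimum(t, c), 10.0)
    event = ((t <= c) & (t <= 10.0)).astype(float)
    return X, time, event


class TestFitLassoCox:
    def test_large_lambda_zeros_penalized(self):
        rng = np.random.default_rng(1)
        X, t, e = _survival(rng, 200, [0.8, -0.5, 0.3])
        beta = fit_lasso_cox(X, t, e, 1e5)
        assert np.all(beta == 0.0)

    def test_large_lambda_keeps_unpenalized(self):
        rng = np.random.default_rng(1)
        X, t, e = _survival(rng, 200, [0.8, -0.5, 0.3])
        beta = fit_lasso_cox(X, t, e, 1e5, unpenalized=[0])
        assert beta[0] != 0.0
        assert np.all(beta[1:] == 0.0)

    def test_lambda_zero_matches_newton(self):
        rng = np.random.default_rng(2)
        X, t, e = _survival(rng, 300, [0.6, -0.4, 0.0, 0.2])
        beta = fit_lasso_cox(X, t, e, 0.0)
        ref = fit_cox(X - X.mean(axis=0), t, e).coefficients
        assert np.max(np.abs(beta - ref)) < 1e-6

    def test_single_covariate_matches_1d_grid_oracle(self):
        rng = np.random.default_rng(3)
        n = 40
        x = rng.standard_normal(n)
        t = rng.exponential(np.exp(-0.9 * x) * 5.0)
        e = np.ones(n)
        lam = 3.0
        beta = fit_lasso_cox(x[:, None], t, e, lam)[0]
        grid = np.arange(-2.0, 2.0, 1e-4)
        b_star = lasso_cox_1d_grid(x, t, e, lam, grid)
        assert beta == pytest.approx(b_star, abs=2e-4)

    def test_zero_events_errors(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 2))
        with pytest.raises(ValueError, match="event"):
            fit_lasso_cox(X, np.ones(20), np.zeros(20), 1.0)

    def test_nonfinite_errors(self):
        X = np.array([[1.0], [np.inf]])
        with pytest.raises(ValueError, match="finite"):
            fit_lasso_cox(X, np.array([1.0, 2.0]), np.array([1.0, 1.0]), 1.0)

    def test_negative_lambda_errors(self):
        rng = np.random.default_rng(5)
        X, t, e = _survival(rng, 50, [0.5])
        with pytest.raises(ValueError, match="lambda"):
            fit_lasso_cox(X, t, e, -1.0)


class TestCVSelectLambda:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X, t, e = _survival(rng, 300, [0.0] * 5)
        cfg = SelectionConfig(n_lambda=12, lambda_decades=2.0, seed=7)
        a = cv_select_lambda(X, t, e, cfg)
        b = cv_select_lambda(X, t, e, cfg)
        assert a.lambda_star == b.lambda_star
        assert np.allclose(a.mean_deviance, b.mean_deviance)

    def test_null_signal_within_one_se_of_grid_max(self):
        rng = np.random.default_rng(8)
        X, t, e = _survival(rng, 400, [0.0] * 8)
        cfg = SelectionConfig(n_lambda=15, lambda_decades=2.0, seed=8)
        cv = cv_select_lambda(X, t, e, cfg)
        k_min = int(np.argmin(cv.mean_deviance))
        # the null model (largest lambda) is within 1 SE of the minimum
        assert cv.mean_deviance[0] <= cv.mean_deviance[k_min] + cv.se_deviance[k_min]

    def test_strong_protein_admitted_across_seeds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X, t, e = _survival(rng, 2000, [np.log(2.0)] + [0.0] * 4)
            cfg = SelectionConfig(n_lambda=10, lambda_decades=1.5, seed=seed)
            cv = cv_select_lambda(X, t, e, cfg)
            beta = fit_lasso_cox(X, t, e, cv.lambda_star)
            hits += beta[0] != 0.0
        assert hits == 10

    def test_empty_grid_errors(self):
        cfg = SelectionConfig(lambda_grid=np.array([]))
        with pytest.raises(ValueError, match="empty"):
            cfg.validate()


def _single_sex_cohort(n, n_proteins, informative, seed, h0=0.012):
    cfg = SimConfig(n_participants=n, male_fraction=1.0, n_proteins=n_proteins,
                    protein_block_size=5, protein_block_correlation=0.2,
                    informative_male=informative, baseline_hazard_rate=h0,
                    dropout_rate=0.0, missing_rate_range=(0, 0),
                    lod_quantile_range=(0, 0), seed=seed)
    return generate_cohort(cfg)


class TestSelectionConfig:
    def test_threshold_count_paper_rule(self):
        assert SelectionConfig(n_bootstrap=200, frequency_threshold=0.95
                               ).selection_count == 190

    def test_threshold_count_rounds_up(self):
        assert SelectionConfig(n_bootstrap=10, frequency_threshold=0.95
                               ).selection_count == 10
        assert SelectionConfig(n_bootstrap=3, frequency_threshold=0.5
                               ).selection_count == 2

    def test_invalid(self):
        with pytest.raises(ValueError):
            SelectionConfig(n_bootstrap=0).validate()
        with pytest.raises(ValueError):
            SelectionConfig(n_folds=1).validate()
        with pytest.raises(ValueError):
            SelectionConfig(frequency_threshold=0.0).validate()


class TestBootstrapStability:
    def test_frequency_190_selected_189_not(self):
        cfg = SelectionConfig(n_bootstrap=200, frequency_threshold=0.95)
        res = SelectionResult(
            sex_stratum="male",
            frequencies=pd.Series({"A": 190, "B": 189}),
            selected=[p for p, c in {"A": 190, "B": 189}.items()
                      if c >= cfg.selection_count],
            n_bootstrap=200, frequency_threshold=0.95)
        assert res.selected == ["A"]

    def test_single_bootstrap_degenerate(self):
        cohort = _single_sex_cohort(400, 6, {1: np.log(2.5)}, seed=9, h0=0.03)
        cfg = SelectionConfig(n_bootstrap=1, n_folds=5, n_lambda=8,
                              lambda_decades=1.5, seed=9)
        res = bootstrap_stability(cohort, cfg)
        assert set(res.selected) == set(
            res.frequencies.index[res.frequencies == 1])

    def test_threshold_monotone(self):
        cohort = _single_sex_cohort(500, 8, {1: np.log(2.5)}, seed=10, h0=0.03)
        cfg = SelectionConfig(n_bootstrap=10, n_folds=5, n_lambda=8,
                              lambda_decades=1.5, seed=10,
                              frequency_threshold=0.9)
        res = bootstrap_stability(cohort, cfg)
        hi = {p for p, c in res.frequencies.items() if c >= int(np.ceil(0.99 * 10))}
        lo = {p for p, c in res.frequencies.items() if c >= int(np.ceil(0.60 * 10))}
        assert hi <= lo

    def test_frequencies_bounded(self):
        cohort = _single_sex_cohort(400, 5, {1: np.log(2)}, seed=11, h0=0.03)
        cfg = SelectionConfig(n_bootstrap=5, n_folds=4, n_lambda=6,
                              lambda_decades=1.5, seed=11)
        res = bootstrap_stability(cohort, cfg)
        assert res.frequencies.between(0, 5).all()
        assert len(res.per_bootstrap_lambda) == 5

    def test_column_order_invariance(self):
        cohort = _single_sex_cohort(500, 6, {1: np.log(2.5)}, seed=12, h0=0.03)
        cfg = SelectionConfig(n_bootstrap=8, n_folds=5, n_lambda=8,
                              lambda_decades=1.5, seed=12)
        res1 = bootstrap_stability(cohort, cfg)
        perm = ["P0004", "P0001", "P0006", "P0002", "P0005", "P0003"]
        cohort2 = CohortTable(cohort.covariates, cohort.proteins[perm],
                              cohort.lod_flags[perm], cohort.horizon)
        res2 = bootstrap_stability(cohort2, cfg)
        assert set(res1.selected) == set(res2.selected)

    def test_zero_event_stratum_errors(self):
        cohort = _single_sex_cohort(50, 3, {}, seed=13, h0=0.0)
        cfg = SelectionConfig(n_bootstrap=2, n_folds=2)
        with pytest.raises(ValueError, match="zero events"):
            bootstrap_stability(cohort, cfg)

    def test_mixed_sex_stratum_rejected(self, small_cohort):
        cfg = SelectionConfig(n_bootstrap=2, n_folds=2)
        with pytest.raises(ValueError, match="single-sex"):
            bootstrap_stability(small_cohort, cfg)


class TestSexSpecificSelection:
    def _two_sex_cohort(self, seed):
        cfg = SimConfig(n_participants=700, male_fraction=0.5, n_proteins=6,
                        protein_block_size=3, protein_block_correlation=0.1,
                        informative_male={1: np.log(2.5)},
                        informative_female={1: np.log(2.5)},
                        baseline_hazard_rate=0.03, dropout_rate=0.0,
                        missing_rate_range=(0, 0), lod_quantile_range=(0, 0),
                        seed=seed)
        return generate_cohort(cfg)

    def test_identical_strata_identical_selection(self):
        cohort = self._two_sex_cohort(14)
        males = cohort.stratum("male")
        cov_f = males.covariates.copy()
        cov_f["sex"] = "female"
        cov_f["participant_id"] = cov_f["participant_id"] + 10_000
        doubled = CohortTable(
            pd.concat([males.covariates, cov_f], ignore_index=True),
            pd.concat([males.proteins, males.proteins], ignore_index=True),
            pd.concat([males.lod_flags, males.lod_flags], ignore_index=True),
            cohort.horizon)
        cfg = SelectionConfig(n_bootstrap=6, n_folds=5, n_lambda=8,
                              lambda_decades=1.5, seed=14)
        res_m, res_f, overlap = run_sex_specific_selection(doubled, cfg)
        pd.testing.assert_series_equal(res_m.frequencies, res_f.frequencies)
        assert overlap["male_only"] == [] and overlap["female_only"] == []

    def test_swap_symmetry(self):
        cohort = self._two_sex_cohort(15)
        cfg = SelectionConfig(n_bootstrap=5, n_folds=5, n_lambda=8,
                              lambda_decades=1.5, seed=15)
        res_m, res_f, _ = run_sex_specific_selection(cohort, cfg)
        flipped_cov = cohort.covariates.copy()
        flipped_cov["sex"] = np.where(flipped_cov["sex"] == "male",
                                      "female", "male")
        flipped = CohortTable(flipped_cov, cohort.proteins, cohort.lod_flags,
                              cohort.horizon)
        res_m2, res_f2, _ = run_sex_specific_selection(flipped, cfg)
        pd.testing.assert_series_equal(res_m.frequencies, res_f2.frequencies)
        pd.testing.assert_series_equal(res_f.frequencies, res_m2.frequencies)

    def test_missing_stratum_errors(self):
        cohort = self._two_sex_cohort(16)
        males = cohort.stratum("male")
        cfg = SelectionConfig(n_bootstrap=2, n_folds=2)
        with pytest.raises(ValueError, match="female"):
            run_sex_specific_selection(males, cfg)
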