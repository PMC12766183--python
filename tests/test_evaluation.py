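import numpy as np
import pytest

from _oracles import (auc_brute, harrell_c_brute, idi_brute, nri_brute,
                      reclassification_brute)
from proteorisk.evaluation import (calibration_deciles, calibration_slope,
                                   categorical_nri, compare_c, harrell_c, idi,
                                   incremental_c, reclassification_table,
                                   risk_categories, roc_at_horizon)


@pytest.fixture
def censored_toy():
    time = np.array([2.0, 5.0, 3.0, 12.0, 1.0, 6.0, 4.0, 11.0])
    event = np.array([1, 0, 1, 0, 1, 0, 1, 1])
    risk = np.array([0.9, 0.2, 0.6, 0.1, 0.8, 0.3, 0.6, 0.2])
    return time, event, risk


class TestHarrellC:
    def test_constant_risk_is_half(self):
        t = np.arange(1.0, 11.0)
        e = np.ones(10)
        c, lo, hi = harrell_c(t, e, np.full(10, 0.3))
        assert c == 0.5

    def test_perfect_discrimination(self):
        t = np.arange(1.0, 11.0)
        e = np.ones(10)
        c, _, _ = harrell_c(t, e, -t)  # earliest event, highest risk
        assert c == 1.0

    def test_matches_brute_force_with_censoring(self, censored_toy):
        t, e, r = censored_toy
        c, _, _ = harrell_c(t, e, r)
        assert c == pytest.approx(harrell_c_brute(t, e, r), abs=1e-14)

    def test_monotone_transform_invariance(self, censored_toy):
        t, e, r = censored_toy
        c1, _, _ = harrell_c(t, e, r)
        c2, _, _ = harrell_c(t, e, np.exp(3 * r))
        assert c1 == pytest.approx(c2, abs=1e-14)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(5, 40)
        e = (rng.random(40) < 0.7).astype(int)
        r = rng.random(40)  # continuous: no risk ties
        c_pos, _, _ = harrell_c(t, e, r)
        c_neg, _, _ = harrell_c(t, e, -r)
        assert c_pos + c_neg == pytest.approx(1.0, abs=1e-14)

    def test_ci_contains_point(self, censored_toy):
        t, e, r = censored_toy
        c, lo, hi = harrell_c(t, e, r)
        assert lo <= c <= hi

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c(np.array([1.0, 2.0]), np.array([0, 1]), np.array([0.1, 0.2]))

    def test_tied_time_event_vs_censored_is_usable(self):
        # tied time, exactly one event: the event should rank higher
        t = np.array([3.0, 3.0, 1.0])
        e = np.array([1, 0, 1])
        r = np.array([0.8, 0.2, 0.9])
        assert harrell_c(t, e, r)[0] == pytest.approx(harrell_c_brute(t, e, r))
        assert harrell_c(t, e, r)[0] == 1.0


class TestCompareC:
    def test_identity(self, censored_toy):
        t, e, r = censored_toy
        delta, p = compare_c(t, e, r, r)
        assert delta == 0.0
        assert p == 1.0

    def test_antisymmetric(self, censored_toy):
        t, e, r = censored_toy
        rng = np.random.default_rng(0)
        r2 = rng.random(len(t))
        d1, p1 = compare_c(t, e, r, r2)
        d2, p2 = compare_c(t, e, r2, r)
        assert d1 == pytest.approx(-d2, abs=1e-14)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_power_against_informative_predictor(self):
        rng = np.random.default_rng(8)
        n = 2000
        lp = rng.standard_normal(n)
        t = rng.exponential(np.exp(-lp) * 10)
        e = (t <= 10).astype(int)
        t = np.minimum(t, 10)
        noise = rng.standard_normal(n)
        delta, p = compare_c(t, e, noise, lp)
        assert delta > 0.1
        assert p < 1e-3


class TestRiskCategories:
    def test_boundary_left_open(self):
        cats = risk_categories(np.array([0.0, 0.05, 0.050001, 0.10, 0.100001, 0.5]))
        assert cats.tolist() == [0, 0, 1, 1, 2, 2]


class TestNRI:
    def test_identity_zero(self, censored_toy):
        t, e, r = censored_toy
        res = categorical_nri(r, r, t, e, n_boot=50, seed=0)
        assert res.nri_total == 0.0
        assert res.nri_events == 0.0
        assert res.nri_nonevents == 0.0

    def test_hand_enumerated_toy(self):
        # 10 events: 3 up, 1 down; 10 non-events: 2 down, 1 up (uncensored)
        base_e = [0.02] * 10
        new_e = [0.07] * 3 + [0.2] * 0 + [0.02] * 6 + [0.0]  # 3 up, 1 down... build explicitly
        new_e = [0.07, 0.07, 0.2, 0.01, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02]
        base_e[3] = 0.07  # the "down" event starts intermediate
        base_ne = [0.07, 0.07, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02]
        new_ne = [0.02, 0.02, 0.07, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02]
        rb = np.array(base_e + base_ne)
        rn = np.array(new_e + new_ne)
        t = np.array([5.0] * 10 + [12.0] * 10)
        e = np.array([1] * 10 + [0] * 10)
        res = categorical_nri(rb, rn, t, e, n_boot=0)
        assert res.nri_events == pytest.approx(0.2)
        assert res.nri_nonevents == pytest.approx(0.1)
        assert res.nri_total == pytest.approx(0.3)
        exp = nri_brute(rb, rn, e.astype(bool))
        assert res.nri_total == pytest.approx(exp[0], abs=1e-14)

    def test_needs_events_and_nonevents(self):
        t = np.full(5, 5.0)
        with pytest.raises(ValueError):
            categorical_nri(np.full(5, 0.1), np.full(5, 0.2), t, np.ones(5), n_boot=0)

    def test_bootstrap_ci_brackets_point(self):
        rng = np.random.default_rng(9)
        n = 300
        lp = rng.standard_normal(n)
        t = np.where(rng.exponential(np.exp(-lp) * 15, n) < 10, 5.0, 12.0)
        e = (t < 10).astype(int)
        rb = rng.uniform(0, 0.2, n)
        rn = np.clip(rb + 0.05 * lp, 0, 1)
        res = categorical_nri(rb, rn, t, e, n_boot=200, seed=3)
        assert res.ci_total[0] <= res.nri_total <= res.ci_total[1]


class TestIDI:
    def test_identity(self, censored_toy):
        t, e, r = censored_toy
        assert idi(r, r, t, e, n_boot=0).idi == 0.0

    def test_hand_arithmetic_toy(self):
        rb = np.array([0.2, 0.3, 0.2, 0.2])
        rn = np.array([0.4, 0.5, 0.1, 0.1])
        t = np.array([5.0, 5.0, 12.0, 12.0])
        e = np.array([1, 1, 0, 0])
        res = idi(rb, rn, t, e, n_boot=0)
        assert res.idi == pytest.approx((0.45 - 0.1) - (0.25 - 0.2), abs=1e-14)
        assert res.idi == pytest.approx(idi_brute(rb, rn, e.astype(bool)), abs=1e-14)


class TestCalibration:
    def test_deciles_partition(self):
        rng = np.random.default_rng(2)
        n = 105
        r = rng.random(n)
        t = rng.exponential(8, n)
        e = (t < 10).astype(int)
        tab = calibration_deciles(r, np.minimum(t, 10), e)
        assert tab["n"].sum() == n
        assert tab["n"].max() - tab["n"].min() <= 1
        assert (tab["decile"] == np.arange(1, 11)).all()

    def test_constant_risk(self):
        n = 50
        t = np.linspace(1, 12, n)
        e = (t < 10).astype(int)
        tab = calibration_deciles(np.full(n, 0.2), t, e)
        assert (tab["mean_predicted"] == 0.2).all()

    def test_correctly_specified_slope(self):
        rng = np.random.default_rng(6)
        n = 20_000
        lp = 0.8 * rng.standard_normal(n)
        h = 0.006 * np.exp(lp)
        t = rng.exponential(1 / h)
        e = (t <= 10).astype(int)
        risk = 1 - np.exp(-10 * h)
        tab = calibration_deciles(risk, np.minimum(t, 10), e)
        assert 0.9 <= calibration_slope(tab) <= 1.1

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="10"):
            calibration_deciles(np.arange(5) / 5, np.arange(1, 6.0), np.ones(5))


class TestROC:
    def test_perfect_separation(self):
        t = np.array([1.0, 2.0, 11.0, 12.0])
        e = np.array([1, 1, 0, 0])
        _, auc = roc_at_horizon(np.array([0.9, 0.8, 0.1, 0.2]), t, e)
        assert auc == 1.0

    def test_uncensored_matches_pair_counting(self):
        rng = np.random.default_rng(4)
        n = 60
        labels = rng.random(n) < 0.4
        t = np.where(labels, 5.0, 12.0)
        r = np.round(rng.random(n), 1)  # induce ties
        points, auc = roc_at_horizon(r, t, labels.astype(int))
        assert auc == pytest.approx(auc_brute(labels, r), abs=1e-12)

    def test_null_predictor_near_half(self):
        rng = np.random.default_rng(13)
        aucs = []
        for _ in range(20):
            n = 500
            labels = rng.random(n) < 0.3
            t = np.where(labels, 5.0, 12.0)
            _, auc = roc_at_horizon(rng.random(n), t, labels.astype(int))
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.02


class TestReclassification:
    def test_identity_diagonal(self, censored_toy):
        t, e, r = censored_toy
        tab_e, tab_ne = reclassification_table(r, r, t, e)
        for tab in (tab_e, tab_ne):
            off = tab.to_numpy() - np.diag(np.diag(tab.to_numpy()))
            assert np.all(off == 0)

    def test_counts_sum_to_n(self, censored_toy):
        t, e, r = censored_toy
        rng = np.random.default_rng(1)
        r2 = rng.random(len(t))
        tab_e, tab_ne = reclassification_table(r, r2, t, e)
        assert tab_e.to_numpy().sum() + tab_ne.to_numpy().sum() == pytest.approx(len(t))

    def test_uncensored_consistency_with_nri_and_brute(self):
        rng = np.random.default_rng(3)
        n = 40
        labels = rng.random(n) < 0.5
        t = np.where(labels, 5.0, 12.0)
        e = labels.astype(int)
        rb = rng.uniform(0, 0.2, n)
        rn = rng.uniform(0, 0.2, n)
        tab_e, tab_ne = reclassification_table(rb, rn, t, e)
        exp_e, exp_ne = reclassification_brute(rb, rn, labels)
        assert np.allclose(tab_e.to_numpy(), exp_e)
        assert np.allclose(tab_ne.to_numpy(), exp_ne)
        # NRI recomputed from the tables equals categorical_nri exactly
        te = tab_e.to_numpy()
        tne = tab_ne.to_numpy()
        up = np.triu_indices(3, 1)
        down = np.tril_indices(3, -1)
        nri_e = (te[up].sum() - te[down].sum()) / te.sum()
        nri_ne = (tne[down].sum() - tne[up].sum()) / tne.sum()
        res = categorical_nri(rb, rn, t, e, n_boot=0)
        assert res.nri_events == pytest.approx(nri_e, abs=1e-14)
        assert res.nri_nonevents == pytest.approx(nri_ne, abs=1e-14)


class TestIncrementalC:
    def test_redundant_and_null_proteins(self, small_cohort):
        from proteorisk.models import fit_cox, SCORE2_COVARIATES
        males = small_cohort.stratum("male")
        prot = males.proteins.copy()
        # redundant: linear function of base covariates; null: independent noise
        prot["P0007"] = ((males.covariates["age"] - 56) / 8.0
                 + 0.01 * np.random.default_rng(1).standard_normal(len(prot)))
        prot["P0008"] = np.random.default_rng(0).standard_normal(len(prot))
        cov = males.covariates
        base = fit_cox(cov[SCORE2_COVARIATES], cov["follow_up_time"],
                       cov["event"], sex_stratum="male")
        from proteorisk.simulate import CohortTable
        cohort = CohortTable(cov, prot, males.lod_flags, males.horizon)
        tab = incremental_c(base, ["P0007", "P0008", "P0001"], cohort, cohort)
        tab = tab.set_index("protein")
        assert abs(tab.loc["P0007", "delta_c"]) < 0.01
        assert abs(tab.loc["P0008", "delta_c"]) < 0.02
        # the genuinely informative protein dominates
        assert tab.loc["P0001", "delta_c"] > max(
            tab.loc["P0007", "delta_c"], tab.loc["P0008", "delta_c"])
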