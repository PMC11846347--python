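"""Kaplan-Meier, log-rank, ridge Cox, Harrell's C, nested CV, associations."""

import numpy as np
import pandas as pd
import pytest

from imfstat import (
    cox_ridge_fit,
    harrell_c,
    hazard_associations,
    km_fit,
    logrank,
    nested_cv_cindex,
)


def brute_force_cindex(lp, times, events):
    """O(n^2) pair-loop oracle for Harrell's C with censoring."""
    conc = ties = comp = 0
    n = len(lp)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                comp += 1
                if lp[i] > lp[j]:
                    conc += 1
                elif lp[i] == lp[j]:
                    ties += 1
    return (conc + 0.5 * ties) / comp


class TestKaplanMeier:
    def test_worked_product_limit_example(self):
        curve = km_fit(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        np.testing.assert_array_equal(curve.event_times, [1.0, 3.0])
        np.testing.assert_allclose(curve.survival_prob, [2.0 / 3.0, 0.0])
        assert curve.prob_at(0.5) == 1.0
        assert curve.prob_at(2.5) == pytest.approx(2.0 / 3.0)

    def test_all_censored_is_flat_one(self):
        curve = km_fit(np.array([5.0, 7.0]), np.array([0, 0]))
        for t in (1.0, 6.0, 100.0):
            assert curve.prob_at(t) == 1.0

    def test_no_censoring_equals_ecdf_complement(self, rng):
        times = rng.exponential(10.0, 150)
        events = np.ones(150, int)
        curve = km_fit(times, events)
        for t in np.quantile(times, [0.2, 0.5, 0.8]):
            assert curve.prob_at(t) == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_group_argument_splits(self, rng):
        times = rng.exponential(5.0, 40)
        events = np.ones(40, int)
        groups = np.repeat(["a", "b"], 20)
        curves = km_fit(times, events, groups)
        assert set(curves) == {"a", "b"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_fit(np.array([]), np.array([]))


class TestLogRank:
    def test_identical_duplicated_groups_null(self, rng):
        t = rng.exponential(5.0, 30)
        e = (rng.random(30) < 0.7).astype(int)
        times = np.r_[t, t]
        events = np.r_[e, e]
        group = np.repeat(["x", "y"], 30)
        res = logrank(times, events, group)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0, abs=1e-9)
        assert res.df == 1

    def test_two_group_chi2_equals_squared_standardized_oe(self, rng):
        """Internal consistency with the hand-computed O-E statistic."""
        times = np.r_[rng.exponential(5.0, 40), rng.exponential(2.0, 40)]
        events = np.ones(80, int)
        group = np.repeat([0, 1], 40)
        res = logrank(times, events, group)
        # hand computation over pooled event times
        o_minus_e = 0.0
        var = 0.0
        for t in np.unique(times[events == 1]):
            at_risk = times >= t
            n = at_risk.sum()
            n1 = (at_risk & (group == 1)).sum()
            d = ((times == t) & (events == 1)).sum()
            d1 = ((times == t) & (events == 1) & (group == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert res.chi2 == pytest.approx(o_minus_e**2 / var, rel=1e-6)

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError, match="2 groups"):
            logrank(rng.exponential(1, 10), np.ones(10, int), np.zeros(10))


class TestCoxRidge:
    def test_one_dimensional_brute_force_oracle(self):
        """beta-hat equals grid maximization of the partial likelihood."""
        times = np.array([2.0, 4.0, 5.0, 7.0, 9.0, 11.0])
        events = np.ones(6, int)
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])

        def log_partial_likelihood(beta):
            order = np.argsort(times)
            ll = 0.0
            for idx, i in enumerate(order):
                risk = order[idx:]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return ll

        grid = np.linspace(-3, 3, 60001)
        brute = grid[np.argmax([log_partial_likelihood(b) for b in grid])]
        model = cox_ridge_fit(x[:, None], times, events, penalty=0.0)
        assert model.coefficients[0] == pytest.approx(brute, abs=1e-4)

    def test_null_feature_small_coefficient_chance_cindex(self):
        cs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.normal(0, 1, (120, 1))
            t = r.exponential(10.0, 120)
            e = (r.random(120) < 0.7).astype(int)
            model = cox_ridge_fit(x, t, e, penalty=1.0)
            cs.append(harrell_c(model.linear_predictor, t, e))
        assert abs(np.mean(cs) - 0.5) < 0.1

    def test_two_group_log_hazard_ratio_recovered(self):
        """True log-HR 0.7, n=500, penalty -> 0: beta within +-0.15 (median)."""
        errs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = np.repeat([0.0, 1.0], 250)
            t = r.exponential(np.where(x == 1, np.exp(-0.7), 1.0) * 10.0)
            e = np.ones(500, int)
            model = cox_ridge_fit(x[:, None], t, e, penalty=1e-8)
            errs.append(model.coefficients[0] - 0.7)
        assert abs(np.median(errs)) < 0.15

    def test_penalty_monotonically_shrinks_coefficients(self, rng):
        x = rng.normal(0, 1, (100, 5))
        t = rng.exponential(np.exp(-x[:, 0]))
        e = np.ones(100, int)
        norms = [
            np.linalg.norm(cox_ridge_fit(x, t, e, penalty=p).coefficients)
            for p in (0.01, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_no_events_rejected(self, rng):
        with pytest.raises(ValueError, match="events"):
            cox_ridge_fit(rng.normal(0, 1, (10, 2)), rng.exponential(1, 10), np.zeros(10, int))


class TestHarrellC:
    def test_perfect_ordering(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        assert harrell_c(-times, times, np.ones(4, int)) == 1.0

    def test_constant_predictor_is_chance(self):
        times = np.array([1.0, 2.0, 3.0])
        assert harrell_c(np.zeros(3), times, np.ones(3, int)) == 0.5

    def test_matches_brute_force_with_censoring(self):
        for seed in range(8):
            r = np.random.default_rng(seed)
            n = 60
            lp = np.round(r.normal(0, 1, n), 1)  # rounding forces some ties
            t = np.round(r.exponential(5.0, n), 1) + 0.1
            e = (r.random(n) < 0.6).astype(int)
            if not e.any():
                continue
            assert harrell_c(lp, t, e) == brute_force_cindex(lp, t, e)

    def test_invariant_under_increasing_transform(self, rng):
        lp = rng.normal(0, 1, 50)
        t = rng.exponential(5.0, 50)
        e = (rng.random(50) < 0.7).astype(int)
        assert harrell_c(lp, t, e) == harrell_c(np.exp(lp), t, e)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c(np.array([1.0, 2.0]), np.array([3.0, 3.0]), np.array([0, 0]))


class TestNestedCv:
    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(0, 1, (60, 8))
        t = rng.exponential(np.exp(-0.8 * X[:, 0]))
        e = (rng.random(60) < 0.8).astype(int)
        grid = np.array([0.1, 1.0, 10.0])
        r1 = nested_cv_cindex(X, t, e, outer=5, inner=3, penalty_grid=grid, seed=3)
        r2 = nested_cv_cindex(X, t, e, outer=5, inner=3, penalty_grid=grid, seed=3)
        np.testing.assert_array_equal(r1.fold_cindices, r2.fold_cindices)
        np.testing.assert_array_equal(r1.best_penalty_per_fold, r2.best_penalty_per_fold)

    def test_informative_feature_beats_chance(self, rng):
        X = rng.normal(0, 1, (120, 10))
        t = rng.exponential(np.exp(-X[:, 0]))
        e = np.ones(120, int)
        res = nested_cv_cindex(X, t, e, outer=5, inner=3,
                               penalty_grid=np.array([0.1, 1.0, 10.0]), seed=0)
        assert res.mean > 0.6

    def test_too_small_cohort_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            nested_cv_cindex(rng.normal(0, 1, (10, 3)), rng.exponential(1, 10),
                             np.ones(10, int), outer=10)


class TestAssociations:
    def make_cohort(self, rng, n=95):
        stage = rng.integers(1, 5, n).astype(float)
        return pd.DataFrame(
            {
                "stage": stage,
                "time_days": rng.exponential(400.0, n) + 1.0,
                "event": (rng.random(n) < 0.7).astype(int),
            }
        )

    def test_point_biserial_equals_pearson_same_pairs(self, rng):
        from scipy import stats

        cohort = self.make_cohort(rng)
        scores = rng.normal(0, 1, len(cohort))
        res = hazard_associations(scores, cohort)
        late = (cohort["stage"] >= 3).astype(float)
        r_pearson, _ = stats.pearsonr(late, scores)
        assert res["stage_point_biserial"].statistic == pytest.approx(r_pearson, abs=1e-12)

    def test_null_association_near_zero(self):
        rs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            cohort = self.make_cohort(r)
            res = hazard_associations(r.normal(0, 1, len(cohort)), cohort)
            rs.append(res["stage_point_biserial"].statistic)
        assert abs(np.mean(rs)) < 0.15

    def test_informative_score_negative_time_correlation(self, rng):
        n = 200
        lp = rng.normal(0, 1, n)
        times = rng.exponential(np.exp(-lp) * 300.0) + 1.0
        cohort = pd.DataFrame(
            {"stage": np.full(n, np.nan), "time_days": times, "event": np.ones(n, int)}
        )
        res = hazard_associations(np.exp(lp), cohort)
        assert res["time_pearson"].statistic < 0
        assert res["time_pearson"].p < 0.01

    def test_too_few_subjects_rejected(self, rng):
        cohort = self.make_cohort(rng, n=2)
        with pytest.raises(ValueError, match="3 usable"):
            hazard_associations(np.array([1.0, 2.0]), cohort)
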