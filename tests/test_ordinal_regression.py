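"""Proportional-odds fitting and Nagelkerke pseudo-R2 machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from likertdif import (
    DataError,
    FitError,
    GroupAssignment,
    dif_statistics_for_item,
    fit_proportional_odds,
    nagelkerke_r2,
)
from likertdif.ordinal_regression import batch_dif_statistics, proportional_odds_loglik


def simulate_po(n, alpha, beta, rng):
    """Draw from logit P(y >= k) = alpha_k + x beta with x ~ N(0,1)."""
    x = rng.standard_normal((n, len(np.atleast_1d(beta))))
    eta = x @ np.atleast_1d(beta)
    cum = expit(np.asarray(alpha)[None, :] + eta[:, None])
    y = 1 + (rng.random(n)[:, None] < cum).sum(axis=1)
    return y, x


class TestFitProportionalOdds:
    def test_balanced_binary_intercept_zero(self):
        y = np.array([1, 2] * 30)
        fit = fit_proportional_odds(y)
        assert abs(fit.alpha[0]) < 1e-10
        assert fit.n == 60

    def test_statsmodels_cross_check(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(8)
        y, x = simulate_po(400, [1.0, 0.0, -1.0], [1.2], rng)
        mine = fit_proportional_odds(y, x)
        other = OrderedModel(y, x, distr="logit").fit(method="bfgs", disp=False)
        assert abs(mine.loglik - other.llf) < 1e-6
        assert mine.loglik >= other.llf - 1e-8  # Newton at least as converged
        # statsmodels parameterizes P(y<=k) = F(c_k - x b): same slope,
        # intercepts are the negated cutpoints
        assert abs(mine.beta[0] - other.params[0]) < 1e-4

    def test_intercepts_non_increasing(self):
        rng = np.random.default_rng(9)
        y, x = simulate_po(300, [1.5, 0.2, -0.9], [0.7], rng)
        fit = fit_proportional_odds(y, x)
        assert (np.diff(fit.alpha) < 0).all()

    def test_constant_column_rejected(self):
        rng = np.random.default_rng(10)
        y, x = simulate_po(200, [0.5, -0.5], [0.8], rng)
        bad = np.column_stack([x, np.ones(200)])
        with pytest.raises(FitError, match="rank deficient"):
            fit_proportional_odds(y, bad)

    def test_missing_category_rejected(self):
        y = np.array([1, 1, 3, 3, 3, 1])
        with pytest.raises(DataError, match="categories \\[2\\]"):
            fit_proportional_odds(y)

    def test_loglik_matches_direct_evaluation(self):
        rng = np.random.default_rng(11)
        y, x = simulate_po(150, [0.8, -0.4], [0.5, -0.3], rng)
        fit = fit_proportional_odds(y, x)
        direct = proportional_odds_loglik(y, x, fit.alpha, fit.beta, int(y.max()))
        assert abs(fit.loglik - direct) < 1e-10


class TestNagelkerke:
    def test_no_improvement_gives_zero(self):
        assert nagelkerke_r2(-100.0, -100.0, 50) == 0.0

    def test_perfect_fit_reaches_one(self):
        ll0 = 10 * np.log(0.5)
        assert abs(nagelkerke_r2(ll0, 0.0, 10) - 1.0) < 1e-12

    def test_two_line_formula(self):
        ll0, ll1, n = -140.0, -120.0, 200
        cs = 1 - np.exp(2 * (ll0 - ll1) / n)
        expected = cs / (1 - np.exp(2 * ll0 / n))
        assert abs(nagelkerke_r2(ll0, ll1, n) - expected) < 1e-14

    def test_model_below_null_rejected(self):
        with pytest.raises(DataError):
            nagelkerke_r2(-100.0, -101.0, 50)

    @given(
        ll0=st.floats(-500.0, -1.0),
        gain=st.floats(0.0, 100.0),
        extra=st.floats(0.0, 50.0),
        n=st.integers(10, 2000),
    )
    @settings(deadline=None, max_examples=80)
    def test_bounded_and_monotone_in_model_loglik(self, ll0, gain, extra, n):
        gain = min(gain, -ll0)  # log-likelihoods stay <= 0
        extra = min(extra, -ll0 - gain)
        r_small = nagelkerke_r2(ll0, ll0 + gain, n)
        r_big = nagelkerke_r2(ll0, ll0 + gain + extra, n)
        assert 0.0 <= r_small <= r_big <= 1.0


class TestDIFStatistics:
    def test_exchangeable_groups_near_zero(self):
        rng = np.random.default_rng(12)
        y, x = simulate_po(200, [1.0, 0.0, -1.0], [1.0], rng)
        # duplicate identical data under two labels
        y2 = np.concatenate([y, y])
        th = np.concatenate([x[:, 0], x[:, 0]])
        g = GroupAssignment(np.array(["A"] * 200 + ["B"] * 200, dtype=object))
        st = dif_statistics_for_item(y2, th, g)
        assert st.d12 <= 1e-6
        assert st.d23 <= 1e-6

    def test_nested_logliks_and_telescoping(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            y, x = simulate_po(250, [1.2, 0.1, -1.0], [1.1], rng)
            g = GroupAssignment(rng.choice(["A", "B", "C"], size=250))
            st = dif_statistics_for_item(y, x[:, 0], g)
            assert st.loglik0 <= st.loglik1 + 1e-8
            assert st.loglik1 <= st.loglik2 + 1e-8
            assert st.loglik2 <= st.loglik3 + 1e-8
            assert st.d12 >= -1e-6 and st.d23 >= -1e-6
            assert abs(st.d13 - (st.d12 + st.d23)) < 1e-12

    def test_injected_uniform_dif_shows_in_d12(self):
        rng = np.random.default_rng(14)
        n = 500
        theta = rng.standard_normal(2 * n)
        alpha = np.array([1.0, 0.0, -1.0])
        shift = np.concatenate([np.zeros(n), -1.0 * np.ones(n)])  # group B harder
        cum = expit(alpha[None, :] + (1.4 * theta + shift)[:, None])
        y = 1 + (rng.random(2 * n)[:, None] < cum).sum(axis=1)
        g = GroupAssignment(np.array(["A"] * n + ["B"] * n, dtype=object))
        st = dif_statistics_for_item(y, theta, g)
        assert st.d12 > 0.02
        assert st.d12 > st.d23

    def test_permutation_null_rarely_exceeds_001(self):
        rng = np.random.default_rng(15)
        y, x = simulate_po(400, [1.0, 0.0, -1.0], [1.3], rng)
        hits = 0
        reps = 60
        for _ in range(reps):
            g = GroupAssignment(rng.permutation(np.array(["A"] * 200 + ["B"] * 200, dtype=object)))
            st = dif_statistics_for_item(y, x[:, 0], g)
            if st.d12 >= 0.01 or st.d23 >= 0.01:
                hits += 1
        assert hits <= reps * 0.05 + 1

    def test_batch_matches_single_item_path(self):
        rng = np.random.default_rng(16)
        n = 300
        theta = rng.standard_normal(n)
        Y = np.empty((n, 5), dtype=int)
        alpha = np.array([1.0, 0.0, -1.0])
        for j in range(5):
            cum = expit(alpha[None, :] + ((1.0 + 0.2 * j) * theta)[:, None])
            Y[:, j] = 1 + (rng.random(n)[:, None] < cum).sum(axis=1)
        g = GroupAssignment(rng.choice(["A", "B", "C"], size=n))
        ids = [f"i{j}" for j in range(5)]
        batched = batch_dif_statistics(Y, theta, g, ids)
        for j, st in enumerate(batched):
            single = dif_statistics_for_item(Y[:, j], theta, g, ids[j])
            assert abs(st.d12 - single.d12) < 1e-9
            assert abs(st.d23 - single.d23) < 1e-9
            assert abs(st.loglik3 - single.loglik3) < 1e-7

    def test_two_group_reduces_to_single_indicator(self):
        rng = np.random.default_rng(17)
        y, x = simulate_po(300, [1.0, 0.0, -1.0], [1.0], rng)
        g = GroupAssignment(np.array(["A", "B"] * 150, dtype=object))
        st = dif_statistics_for_item(y, x[:, 0], g)
        # Model 2 has exactly theta + one indicator: refit by hand
        ind = (g.labels == "B").astype(float)
        f2 = fit_proportional_odds(y, np.column_stack([x[:, 0], ind]))
        assert abs(f2.loglik - st.loglik2) < 1e-8
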