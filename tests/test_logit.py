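import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import kstest, norm

from mdgsa import (
    CollinearityError,
    DegenerateCovariateError,
    DegenerateSetError,
    InvalidPValueError,
    InvalidStandardErrorError,
    WrongModelError,
    bh_adjust,
    fit_bivariate,
    fit_univariate,
    saddle_point,
    wald_pvalue,
)


def bh_oracle(p):
    """Direct step-up formula, independent of the implementation under test."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def cell_data():
    """2x2 binary covariates, cell (X,Y) -> (members, non-members)."""
    cells = {(0, 0): (10, 90), (1, 0): (20, 80), (0, 1): (30, 70), (1, 1): (60, 40)}
    xs, ys, ms = [], [], []
    for (a, b), (k, n) in cells.items():
        xs += [a] * (k + n)
        ys += [b] * (k + n)
        ms += [1] * k + [0] * n
    return np.column_stack([xs, ys]).astype(float), np.array(ms)


class TestClosedForms:
    def test_univariate_binary_covariate_log_odds_ratio(self):
        # members: 3 at x=1, 1 at x=0; non-members: 5 at x=1, 15 at x=0
        x = np.array([1.0] * 3 + [0.0] + [1.0] * 5 + [0.0] * 15)
        y = np.array([1] * 4 + [0] * 20)
        fit = fit_univariate(x, y)
        assert fit.alpha == pytest.approx(np.log(9), abs=1e-6)
        assert fit.intercept == pytest.approx(np.log(1 / 15), abs=1e-6)
        assert fit.converged

    def test_bivariate_saturated_log_odds_contrasts(self):
        xy, member = cell_data()
        fit = fit_bivariate(xy, member)
        assert fit.intercept == pytest.approx(np.log(10 / 90), abs=1e-6)
        assert fit.alpha == pytest.approx(np.log(2.25), abs=1e-6)
        assert fit.beta == pytest.approx(np.log((30 / 70) / (10 / 90)), abs=1e-6)
        gamma = (
            np.log(60 / 40) - np.log(30 / 70) - np.log(20 / 80) + np.log(10 / 90)
        )
        assert fit.gamma == pytest.approx(gamma, abs=1e-6)

    def test_bivariate_matches_brute_force_likelihood_maximizer(self):
        xy, member = cell_data()
        fit = fit_bivariate(xy, member)
        X = np.column_stack(
            [np.ones(len(member)), xy[:, 0], xy[:, 1], xy[:, 0] * xy[:, 1]]
        )

        def nll(coef):
            eta = X @ coef
            return -np.sum(member * eta - np.logaddexp(0.0, eta))

        res = minimize(nll, np.zeros(4), method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        np.testing.assert_allclose(
            [fit.intercept, fit.alpha, fit.beta, fit.gamma], res.x, atol=1e-5
        )

    def test_matches_statsmodels_on_continuous_data(self, rng):
        import statsmodels.api as sm

        xy = rng.standard_normal((2000, 2))
        eta = -2.0 + 0.5 * xy[:, 0] - 0.3 * xy[:, 1] + 0.4 * xy[:, 0] * xy[:, 1]
        member = (rng.random(2000) < expit(eta)).astype(int)
        fit = fit_bivariate(xy, member)
        X = sm.add_constant(
            np.column_stack([xy, xy[:, 0] * xy[:, 1]])
        )
        ref = sm.Logit(member, X).fit(disp=0)
        np.testing.assert_allclose(
            [fit.intercept, fit.alpha, fit.beta, fit.gamma], ref.params, atol=1e-6
        )
        np.testing.assert_allclose(
            [fit.se_intercept, fit.se_alpha, fit.se_beta, fit.se_gamma],
            ref.bse,
            atol=1e-6,
        )


class TestSymmetryNulls:
    def test_univariate_sign_symmetric_configuration(self):
        # members at {-1, +1}, non-members at {-2, +2}, balanced
        x = np.array([-1.0, 1.0, -2.0, 2.0] * 5)
        y = np.array([1, 1, 0, 0] * 5)
        fit = fit_univariate(x, y)
        assert abs(fit.alpha) < 1e-8

    def test_bivariate_fully_symmetric_configuration(self):
        pts_m = [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        pts_n = [(-2, -2), (-2, 2), (2, -2), (2, 2)]
        xy = np.array(pts_m + pts_n, float)
        member = np.array([1] * 4 + [0] * 4)
        fit = fit_bivariate(xy, member)
        assert abs(fit.alpha) < 1e-8
        assert abs(fit.beta) < 1e-8
        assert abs(fit.gamma) < 1e-8
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)  # logit(1/2)


class TestFitProperties:
    def test_affine_equivariance_of_alpha(self, rng):
        x = rng.standard_normal(500)
        member = (rng.random(500) < expit(-1.0 + 0.8 * x)).astype(int)
        fit = fit_univariate(x, member)
        sd = x.std(ddof=1)
        fit_std = fit_univariate((x - x.mean()) / sd, member)
        assert fit_std.alpha == pytest.approx(fit.alpha * sd, rel=1e-6)
        assert fit_std.p_alpha == pytest.approx(fit.p_alpha, abs=1e-8)

    def test_shifting_member_values_does_not_decrease_alpha(self, rng):
        x = rng.standard_normal(500)
        member = (rng.random(500) < 0.1).astype(int)
        base = fit_univariate(x, member).alpha
        x2 = x.copy()
        x2[member == 1] += 0.5
        assert fit_univariate(x2, member).alpha >= base

    def test_null_wald_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(200):
            x = rng.standard_normal(500)
            member = np.zeros(500, dtype=int)
            member[rng.choice(500, 40, replace=False)] = 1
            pvals.append(fit_univariate(x, member).p_alpha)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_complete_separation_reported_with_huge_se(self):
        # deviance plateaus at ~0, so the fit "converges" but the Wald test
        # is harmless: the standard error explodes and p is ~1
        x = np.concatenate([np.ones(20) * 5, -np.ones(80) * 5])
        member = np.concatenate([np.ones(20, int), np.zeros(80, int)])
        fit = fit_univariate(x, member)
        assert fit.se_alpha > 100
        assert fit.p_alpha > 0.99

    def test_quasi_separation_flagged_not_raised(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        member = np.zeros(200, int)
        member[np.argsort(x)[-8:]] = 1  # members are the 8 largest values
        fit = fit_univariate(x, member)
        assert not fit.converged
        assert fit.n_iterations == 25

    def test_deviance_bounded_by_null_deviance(self, rng):
        x = rng.standard_normal(300)
        member = (rng.random(300) < 0.2).astype(int)
        fit = fit_univariate(x, member)
        assert 0 <= fit.deviance <= fit.null_deviance


class TestFitErrors:
    def test_single_class_membership(self, rng):
        with pytest.raises(DegenerateSetError):
            fit_univariate(rng.standard_normal(10), np.ones(10, int))

    def test_zero_variance_covariate(self):
        with pytest.raises(DegenerateCovariateError):
            fit_univariate(np.ones(10), np.array([1] * 3 + [0] * 7))

    def test_collinear_design(self, rng):
        x = rng.standard_normal(100)
        xy = np.column_stack([x, 2.0 * x])
        with pytest.raises(CollinearityError):
            fit_bivariate(xy, np.array([1] * 20 + [0] * 80))


class TestWald:
    @pytest.mark.parametrize(
        ("coef", "se", "expected"),
        [
            (0.0, 1.0, 1.0),
            (1.959964, 1.0, 0.05),
            (-1.959964, 1.0, 0.05),
        ],
    )
    def test_reference_values(self, coef, se, expected):
        assert wald_pvalue(coef, se) == pytest.approx(expected, abs=1e-4)

    def test_matches_normal_cdf(self):
        assert wald_pvalue(1.3, 0.5) == pytest.approx(2 * norm.sf(2.6))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(InvalidStandardErrorError):
            wald_pvalue(1.0, 0.0)


class TestBhAdjust:
    def test_worked_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        assert bh_adjust([0.5])[0] == 0.5

    def test_invalid_input(self):
        with pytest.raises(InvalidPValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=300, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_step_up_oracle_and_bounds(self, pvals):
        adj = bh_adjust(pvals)
        np.testing.assert_allclose(adj, bh_oracle(pvals), atol=1e-12)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= np.minimum(1.0, p * p.size) + 1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=20),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance_and_order_preservation(self, pvals, rand):
        perm = list(range(len(pvals)))
        rand.shuffle(perm)
        adj = bh_adjust(pvals)
        adj_perm = bh_adjust([pvals[i] for i in perm])
        np.testing.assert_allclose(adj_perm, adj[perm], atol=1e-12)
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestSaddlePoint:
    def test_direct_substitution(self):
        fit = fit_bivariate(*cell_data())
        fit.alpha, fit.beta, fit.gamma = 1.0, 2.0, 0.5
        sp = saddle_point(fit)
        assert (sp.x0, sp.y0) == (-4.0, -2.0)
        assert sp.defined

    def test_pure_interaction_saddle_at_origin(self):
        fit = fit_bivariate(*cell_data())
        fit.alpha, fit.beta, fit.gamma = 0.0, 0.0, 1.0
        sp = saddle_point(fit)
        assert (sp.x0, sp.y0) == (0.0, 0.0)

    def test_zero_interaction_is_undefined(self):
        fit = fit_bivariate(*cell_data())
        fit.gamma = 0.0
        assert not saddle_point(fit).defined

    def test_univariate_fit_rejected(self, rng):
        x = rng.standard_normal(100)
        fit = fit_univariate(x, np.array([1] * 20 + [0] * 80))
        with pytest.raises(WrongModelError):
            saddle_point(fit)
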