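import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from heckcrash.exceptions import (CollinearityError, InvalidInputError,
                                  SeparationError)
from heckcrash.probit_stage import (fit_probit, inverse_mills,
                                    mills_from_fit, probit_loglik)
from heckcrash.synthetic_data import simulate_dataset

from conftest import compact_config


class TestProbitLoglik:
    def test_zero_coefficients_give_n_log_half(self):
        rng = np.random.default_rng(0)
        Z = np.column_stack([np.ones(17), rng.normal(size=17)])
        s = rng.binomial(1, 0.5, 17)
        assert probit_loglik(np.zeros(2), Z, s) == pytest.approx(
            17 * np.log(0.5))

    def test_three_row_toy_against_normal_cdf(self):
        # intercept-only design scaled to give indices (-1, 0, 2)
        Z = np.array([[-1.0], [0.0], [2.0]])
        s = np.array([0, 1, 1])
        expected = (np.log(1 - norm.cdf(-1)) + np.log(norm.cdf(0))
                    + np.log(norm.cdf(2)))
        assert probit_loglik([1.0], Z, s) == pytest.approx(expected,
                                                           rel=1e-12)

    def test_extreme_index_stays_finite(self):
        Z = np.array([[1.0]])
        s = np.array([1])
        val = probit_loglik([-40.0], Z, s)
        assert np.isfinite(val)
        # log Phi(-40) ~ -(40^2)/2 - log(40 sqrt(2 pi))
        approx = -800.0 - np.log(40 * np.sqrt(2 * np.pi))
        assert val == pytest.approx(approx, rel=1e-3)

    def test_non_binary_indicator_rejected(self):
        with pytest.raises(InvalidInputError):
            probit_loglik([0.0], np.ones((3, 1)), np.array([0, 1, 2]))


class TestFitProbit:
    def test_symmetric_data_give_zero_intercept(self):
        # duplicating every noisy row with (z, s) -> (-z, 1-s) makes the
        # sample exactly sign-symmetric, forcing a zero intercept
        rng = np.random.default_rng(23)
        z = rng.normal(size=150)
        s = (0.8 * z + rng.normal(size=150) > 0).astype(int)
        Zb = np.vstack([np.column_stack([np.ones_like(z), z]),
                        np.column_stack([np.ones_like(z), -z])])
        sb = np.concatenate([s, 1 - s])
        fit = fit_probit(Zb, sb)
        assert fit.gamma_hat[0] == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_within_three_se(self):
        ds = simulate_dataset(compact_config(5000, rho=0.0, seed=13))
        d = ds.design()
        fit = fit_probit(d.Z, d.s)
        err = np.abs(fit.gamma_hat - ds.truth.gamma_true)
        assert (err < 3 * fit.se).all()

    def test_matches_independent_probit_implementation(self):
        sm = pytest.importorskip("statsmodels.api")
        ds = simulate_dataset(compact_config(2000, rho=0.0, seed=14))
        d = ds.design()
        ours = fit_probit(d.Z, d.s)
        ref = sm.Probit(d.s, d.Z).fit(disp=0)
        assert np.allclose(ours.gamma_hat, ref.params, atol=1e-6)
        assert np.allclose(ours.se, ref.bse, rtol=1e-4)

    def test_one_class_outcome_raises_separation(self):
        Z = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(SeparationError):
            fit_probit(Z, np.ones(10))

    def test_perfectly_separated_data_raise(self):
        z = np.concatenate([np.linspace(-3, -1, 20), np.linspace(1, 3, 20)])
        Z = np.column_stack([np.ones_like(z), z])
        s = (z > 0).astype(int)
        with pytest.raises(SeparationError):
            fit_probit(Z, s)

    def test_rank_deficient_design_raises(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        Z = np.column_stack([np.ones(50), x, 2 * x])
        s = rng.binomial(1, 0.5, 50)
        with pytest.raises(CollinearityError):
            fit_probit(Z, s)

    def test_loglik_nonpositive_and_gradient_small(self):
        ds = simulate_dataset(compact_config(1000, rho=0.0, seed=15))
        d = ds.design()
        fit = fit_probit(d.Z, d.s)
        assert fit.converged
        assert fit.loglik <= 0

    def test_concavity_unique_optimum_vs_grid(self):
        # 2-parameter toy: Newton answer beats every point of a dense grid
        rng = np.random.default_rng(16)
        z = rng.normal(size=200)
        Z = np.column_stack([np.ones(200), z])
        s = (0.3 + 0.8 * z + rng.normal(size=200) > 0).astype(int)
        fit = fit_probit(Z, s)
        g0 = np.linspace(fit.gamma_hat[0] - 1, fit.gamma_hat[0] + 1, 200)
        g1 = np.linspace(fit.gamma_hat[1] - 1, fit.gamma_hat[1] + 1, 200)
        best = -np.inf
        arg = None
        for a in g0:
            lls = [probit_loglik([a, b], Z, s) for b in g1]
            j = int(np.argmax(lls))
            if lls[j] > best:
                best, arg = lls[j], (a, g1[j])
        assert fit.loglik >= best - 1e-9
        res = max(g0[1] - g0[0], g1[1] - g1[0])
        assert abs(fit.gamma_hat[0] - arg[0]) <= res
        assert abs(fit.gamma_hat[1] - arg[1]) <= res


class TestInverseMills:
    def test_value_at_zero(self):
        assert inverse_mills(0.0) == pytest.approx(np.sqrt(2 / np.pi),
                                                   abs=1e-10)

    def test_value_at_one_point_five(self):
        expected = norm.pdf(1.5) / norm.cdf(1.5)     # 0.12952/0.93319
        assert inverse_mills(1.5) == pytest.approx(expected, rel=1e-12)
        assert inverse_mills(1.5) == pytest.approx(0.1388, abs=5e-5)

    def test_deep_tail_asymptote(self):
        # lambda(a) ~ -a + 1/(-a) for a -> -inf
        assert inverse_mills(-30.0) == pytest.approx(30.0 + 1 / 30.0,
                                                     abs=1e-4)
        assert np.isfinite(inverse_mills(-300.0))

    def test_branch_continuity_at_switch(self):
        lo, hi = inverse_mills(-25.0 - 1e-9), inverse_mills(-25.0 + 1e-9)
        assert lo == pytest.approx(hi, rel=1e-7)

    def test_nan_rejected(self):
        with pytest.raises(InvalidInputError):
            inverse_mills(np.nan)

    @given(st.floats(-200, 38))
    @settings(max_examples=200, deadline=None)
    def test_positive_and_delta_in_unit_interval(self, a):
        lam = inverse_mills(a)
        assert lam > 0
        delta = lam * (lam + a)
        assert 0 < delta < 1

    def test_strictly_decreasing_on_grid(self):
        grid = np.linspace(-40, 8, 4001)
        vals = inverse_mills(grid)
        assert (np.diff(vals) < 0).all()


class TestMillsFromFit:
    def test_constant_zero_index_gives_avg_sqrt_2_over_pi(self):
        rng = np.random.default_rng(17)
        Z = np.ones((400, 1))
        s = rng.binomial(1, 0.5, 400)
        # balance exactly so gamma_hat = 0
        s = np.array([0, 1] * 200)
        fit = fit_probit(Z, s)
        mills = mills_from_fit(fit, s == 1)
        assert mills.average_mills == pytest.approx(np.sqrt(2 / np.pi),
                                                    abs=1e-6)

    def test_delta_in_unit_interval_for_fit(self, compact_dataset):
        d = compact_dataset.design()
        fit = fit_probit(d.Z, d.s)
        mills = mills_from_fit(fit, d.s == 1)
        assert ((mills.delta_i > 0) & (mills.delta_i < 1)).all()
        assert (mills.lambda_i > 0).all()

    def test_no_selected_rows_rejected(self, compact_dataset):
        d = compact_dataset.design()
        fit = fit_probit(d.Z, d.s)
        with pytest.raises(InvalidInputError):
            mills_from_fit(fit, np.zeros(d.n, dtype=bool))
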