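import numpy as np
import pytest
from scipy import optimize

from tailorcut import (ParameterSet, SimConfig, fit_baseline, fit_ml,
                       generate_dataset, parse_model, robust_correction)
from conftest import random_covariance


def _fml(sigma, S):
    p = S.shape[0]
    return (np.linalg.slogdet(sigma)[1] - np.linalg.slogdet(S)[1]
            + np.trace(S @ np.linalg.inv(sigma)) - p)


class TestFitML:
    def test_saturated_model_fits_exactly(self, rng):
        m = parse_model("f1 =~ x1 + x2 + x3")
        S = random_covariance(rng, 3)
        fit = fit_ml(m, S, 200)
        assert fit.df == 0
        assert fit.T == 0.0
        assert np.allclose(fit.implied, S, atol=1e-8)

    def test_matches_generic_optimizer_reminimization(self, rng):
        """L-BFGS solution agrees with an independent Nelder-Mead
        re-minimization of F_ML from the same starting point."""
        m = parse_model("f1 =~ x1 + x2 + x3 + x4 + x5")
        pop = ParameterSet(np.full((5, 1), 0.7), np.eye(1), np.eye(5) * 0.51)
        x = generate_dataset(pop, SimConfig(n=300, master_seed=42), 0)
        S = np.cov(x, rowvar=False, ddof=0)
        fit = fit_ml(m, S, 300)
        assert fit.converged

        def obj(v):
            ps = m.build_matrices(v)
            sigma = ps.implied_covariance()
            try:
                np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                return 1e9
            return _fml(sigma, S)

        res = optimize.minimize(obj, fit.free_values * 1.3,
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14,
                                         "maxiter": 20000, "maxfev": 20000})
        assert 300 * res.fun == pytest.approx(fit.T, abs=1e-6)

    def test_heywood_case_flagged_not_raised(self):
        # correlation pattern forcing a negative residual variance on x1
        S = np.array([[1.0, 0.9, 0.9],
                      [0.9, 1.0, 0.8],
                      [0.9, 0.8, 1.0]])
        fit = fit_ml(parse_model("f1 =~ x1 + x2 + x3"), S, 100)
        assert fit.converged and not fit.proper

    def test_singular_s_rejected(self):
        m = parse_model("f1 =~ x1 + x2 + x3")
        S = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            fit_ml(m, S, 100)

    def test_wishart_multiplier_option(self):
        m = parse_model("f1 =~ x1 + x2 + x3 + x4")
        pop = ParameterSet(np.full((4, 1), 0.7), np.eye(1), np.eye(4) * 0.51)
        x = generate_dataset(pop, SimConfig(n=100, master_seed=6), 0)
        S = np.cov(x, rowvar=False, ddof=0)
        f_n = fit_ml(m, S, 100, multiplier="n")
        f_w = fit_ml(m, S, 100, multiplier="n-1")
        assert f_n.converged and f_w.converged
        assert f_w.T == pytest.approx(f_n.T * 99 / 100, rel=1e-7)

    def test_statistic_invariant_to_item_reordering(self, rng):
        text = "f1 =~ x1 + x2 + x3\nf2 =~ x4 + x5 + x6"
        m = parse_model(text)
        pop = ParameterSet(
            np.array([[.7, 0], [.6, 0], [.8, 0], [0, .7], [0, .6], [0, .5]]),
            np.array([[1, .3], [.3, 1]]), np.diag(np.full(6, .5)),
            [f"x{i}" for i in range(1, 7)])
        x = generate_dataset(pop, SimConfig(n=400, master_seed=8), 0)
        S = np.cov(x, rowvar=False, ddof=0)
        T1 = fit_ml(m, S, 400).T
        perm = [2, 0, 1, 5, 3, 4]   # reorder within factors
        m_p = parse_model("f1 =~ x3 + x1 + x2\nf2 =~ x6 + x4 + x5")
        T2 = fit_ml(m_p, S[np.ix_(perm, perm)], 400).T
        assert T2 == pytest.approx(T1, abs=1e-6)

    def test_statistic_invariant_to_common_rescaling(self):
        m = parse_model("f1 =~ x1 + x2 + x3 + x4 + x5")
        pop = ParameterSet(np.full((5, 1), 0.7), np.eye(1), np.eye(5) * 0.51)
        x = generate_dataset(pop, SimConfig(n=250, master_seed=14), 0)
        S = np.cov(x, rowvar=False, ddof=0)
        f1 = fit_ml(m, S, 250)
        f2 = fit_ml(m, 4.0 * S, 250)
        assert f1.converged and f2.converged
        assert f2.T == pytest.approx(f1.T, abs=1e-6)

    def test_structureless_covariance_flagged_nonconverged(self, rng):
        # pure Wishart noise has no common factor: the likelihood is flat
        # along the loading/variance ridge and the fit must say so rather
        # than report a spurious optimum
        m = parse_model("f1 =~ x1 + x2 + x3 + x4 + x5")
        S = random_covariance(rng, 5)
        fit = fit_ml(m, S, 250)
        assert not fit.converged or fit.grad_norm < 1e-6


class TestBaseline:
    def test_diagonal_s_zero_statistic(self):
        T_b, df_b = fit_baseline(np.diag([1.0, 2.0, 3.0]), 100)
        assert T_b == 0.0 and df_b == 3

    def test_two_variable_closed_form(self):
        T_b, df_b = fit_baseline(np.array([[2.0, 1.0], [1.0, 2.0]]), 100)
        assert T_b == pytest.approx(100 * (np.log(4) - np.log(3)))
        assert T_b == pytest.approx(28.768, abs=0.01)
        assert df_b == 1

    def test_closed_form_equals_numerical_optimization(self, rng):
        for _ in range(5):
            p = int(rng.integers(3, 6))
            S = random_covariance(rng, p)
            T_b, _ = fit_baseline(S, 150)

            def obj(logd):
                return _fml(np.diag(np.exp(logd)), S)

            res = optimize.minimize(obj, np.log(np.diag(S)) + 0.3,
                                    method="BFGS", options={"gtol": 1e-12})
            assert T_b == pytest.approx(150 * res.fun, abs=1e-8)


class TestRobustCorrection:
    def test_df_zero_refuses_to_scale(self, rng):
        m = parse_model("f1 =~ x1 + x2 + x3")
        pop = ParameterSet(np.full((3, 1), 0.7), np.eye(1), np.eye(3) * 0.51)
        x = generate_dataset(pop, SimConfig(n=200, master_seed=1), 0)
        fit = fit_ml(m, np.cov(x, rowvar=False, ddof=0), 200)
        fit = robust_correction(x, m, fit)
        assert fit.c == 1.0 and fit.T_scaled == fit.T == 0.0

    def test_normal_data_scaling_factor_near_one(self):
        m = parse_model("f1 =~ x1 + x2 + x3 + x4 + x5")
        pop = ParameterSet(np.full((5, 1), 0.7), np.eye(1), np.eye(5) * 0.51)
        x = generate_dataset(pop, SimConfig(n=10**5, master_seed=21), 0)
        fit = fit_ml(m, np.cov(x, rowvar=False, ddof=0), 10**5)
        fit = robust_correction(x, m, fit)
        assert fit.c == pytest.approx(1.0, abs=0.05)

    def test_baseline_scaling_factor_near_one_when_baseline_true(self):
        # the baseline scaling factor has its c -> 1 normal-theory limit
        # only when the independence model is itself correct
        m = parse_model("f1 =~ x1 + x2 + x3 + x4 + x5")
        pop = ParameterSet(np.zeros((5, 1)), np.eye(1),
                           np.diag([0.5, 0.8, 1.0, 1.3, 2.0]))
        x = generate_dataset(pop, SimConfig(n=10**5, master_seed=22), 0)
        fit = fit_ml(m, np.cov(x, rowvar=False, ddof=0), 10**5)
        fit = robust_correction(x, m, fit)
        assert fit.baseline_c == pytest.approx(1.0, abs=0.05)

    def test_dimension_mismatch(self, rng):
        m = parse_model("f1 =~ x1 + x2 + x3 + x4")
        S = random_covariance(rng, 4)
        fit = fit_ml(m, S, 100)
        with pytest.raises(ValueError, match="width"):
            robust_correction(rng.standard_normal((100, 3)), m, fit)

    def test_small_n_warns(self, rng):
        m = parse_model("f1 =~ x1 + x2 + x3 + x4 + x5")
        pop = ParameterSet(np.full((5, 1), 0.7), np.eye(1), np.eye(5) * 0.51)
        x = generate_dataset(pop, SimConfig(n=12, master_seed=2), 0)
        fit = fit_ml(m, np.cov(x, rowvar=False, ddof=0), 12)
        if fit.converged:
            with pytest.warns(UserWarning, match="moments"):
                robust_correction(x, m, fit)
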