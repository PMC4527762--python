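"""Optimal linear predictive coding: closed form vs. independent oracles."""

import math

import numpy as np
import pytest
from scipy.linalg import solve_toeplitz
from scipy.optimize import minimize

from predcode.linear_theory import (
    EnsembleParams,
    beta_of_tau,
    input_power_spectrum,
    lambda_star,
    optimal_solution,
    optimal_weights,
    output_spectrum,
    prediction_error_filter,
    theoretical_gain,
    theoretical_gain_closed_form,
)
from predcode.signals import gen_correlated_signal, gen_white_noise, mix_snr


def analytic_autocovariance(beta: float, sigma: float, max_lag: int) -> np.ndarray:
    """Population autocovariance of the signal+noise mixture (power 1)."""
    lags = np.arange(max_lag + 1)
    if math.isinf(sigma):
        return beta ** lags.astype(float)
    rho = (sigma / (1 + sigma)) * beta ** lags.astype(float)
    rho[0] += 1.0 / (1 + sigma)
    return rho


def population_wiener(beta: float, sigma: float, N: int) -> np.ndarray:
    """Exact minimizer of the expected network gain over N-tap predictors.

    Solves the normal equations with the analytic autocovariance — an oracle
    fully independent of the closed-form Lambda* solution.
    """
    rho = analytic_autocovariance(beta, sigma, N)
    return solve_toeplitz((rho[:N], rho[:N]), rho[1 : N + 1])


def sample_wiener(f: np.ndarray, N: int) -> np.ndarray:
    """Exact minimizer of the *empirical* network gain over N-tap predictors."""
    n = f.size
    nfft = 1 << (2 * n - 1).bit_length()
    F = np.fft.rfft(f, nfft)
    ac = np.fft.irfft(F * np.conj(F), nfft)[: N + 1] / n
    return solve_toeplitz((ac[:N], ac[:N]), ac[1 : N + 1])


def simulate_ensemble(beta: float, sigma: float, n: int, seed: int) -> np.ndarray:
    tau = -1.0 / math.log(beta)
    s = gen_correlated_signal(tau, n, seed)
    e = gen_white_noise(n, 1.0, seed + 1)
    return mix_snr(s, e, sigma)


class TestBetaOfTau:
    def test_value_at_tau_one(self):
        assert beta_of_tau(1.0) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_limits_and_monotonicity(self):
        assert beta_of_tau(1e-6) < 1e-6
        assert beta_of_tau(1e9) > 1 - 1e-8
        taus = np.linspace(0.1, 50, 100)
        betas = [beta_of_tau(t) for t in taus]
        assert np.all(np.diff(betas) > 0)

    def test_nonpositive_tau_raises(self):
        with pytest.raises(ValueError):
            beta_of_tau(0.0)


class TestLambdaStar:
    @pytest.mark.parametrize("beta", [0.3, 0.6, 0.9])
    def test_zero_snr_limit_predicts_nothing(self, beta):
        assert lambda_star(beta, 0.0) == 0.0
        assert lambda_star(beta, 1e-10) < 1e-8

    @pytest.mark.parametrize("beta", [0.3, 0.6, 0.9])
    def test_infinite_snr_limit_full_prediction(self, beta):
        assert lambda_star(beta, math.inf) == 1.0
        assert lambda_star(beta, 1e10) == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("beta", [0.3, 0.6, 0.9])
    def test_monotone_nondecreasing_in_snr(self, beta):
        sig = np.concatenate(([0.0], np.logspace(-3, 3, 200)))
        lam = np.array([lambda_star(beta, s) for s in sig])
        assert np.all(np.diff(lam) >= 0)
        assert np.all((lam >= 0) & (lam < 1))

    @pytest.mark.parametrize("beta", [-0.1, 0.0, 1.0, 1.5])
    def test_invalid_beta_raises(self, beta):
        with pytest.raises(ValueError):
            lambda_star(beta, 1.0)

    def test_matches_population_wiener_on_grid(self):
        # The exact minimizer of the expected gain (normal equations on the
        # analytic autocovariance) must reproduce the closed-form geometric
        # weights across the whole (beta, sigma) grid.
        for beta in (0.3, 0.6, 0.9):
            for sigma in (0.1, 1.0, 10.0):
                w_oracle = population_wiener(beta, sigma, 30)
                w = optimal_weights(beta, sigma, 30)
                assert np.linalg.norm(w_oracle - w) <= 0.02 * np.linalg.norm(w)


class TestOptimalWeights:
    def test_zero_snr_gives_zero_weights(self):
        np.testing.assert_array_equal(optimal_weights(0.5, 0.0, 10), np.zeros(10))

    @pytest.mark.parametrize("beta,sigma", [(0.3, 0.5), (0.6, 2.0), (0.9, 10.0)])
    def test_geometric_ratio(self, beta, sigma):
        w = optimal_weights(beta, sigma, 5)
        lam = lambda_star(beta, sigma)
        assert w[1] / w[0] == pytest.approx(beta * (1 - lam), rel=1e-12)

    def test_invalid_length_raises(self):
        with pytest.raises(ValueError):
            optimal_weights(0.5, 1.0, 0)

    def test_direct_minimization_of_simulated_gain(self):
        # Brute-force oracle: the exact minimizer of the simulated (sample)
        # network gain. The series is long enough that the estimator's
        # sampling error (~sqrt(30)*sigma_p/sqrt(n)) sits below the 2% bar.
        beta, sigma = 0.5, 1.0
        f = simulate_ensemble(beta, sigma, 4 * 10**6, seed=2)
        w_hat = sample_wiener(f, 30)
        w = optimal_weights(beta, sigma, 30)
        assert np.linalg.norm(w_hat - w) <= 0.02 * np.linalg.norm(w)

    def test_scipy_minimizer_agrees_with_closed_form(self):
        # Independent numerical route: generic quasi-Newton minimization of
        # the analytic-spectrum gain over a 12-tap weight vector.
        beta, sigma = 0.5, 1.0
        params = EnsembleParams(beta, sigma)
        res = minimize(
            lambda w: theoretical_gain(params, w, n_freq=512),
            np.zeros(12),
            method="L-BFGS-B",
            options={"ftol": 1e-14, "gtol": 1e-10},
        )
        w = optimal_weights(beta, sigma, 12)
        assert np.linalg.norm(res.x - w) <= 0.02 * np.linalg.norm(w)

    def test_truncated_solution_tail_below_tolerance(self):
        sol = optimal_solution(0.9, 10.0, tol=1e-12)
        r = 0.9 * (1 - sol.lambda_star)
        tail = sol.weights[-1] * r / (1 - r)
        assert tail < 1e-12
        assert sol.truncation_N == sol.weights.size


class TestPredictionErrorFilter:
    def test_zero_weights_is_identity(self, rng):
        f = rng.standard_normal(100)
        np.testing.assert_array_equal(prediction_error_filter(f, np.zeros(5)), f)

    def test_constant_input_cancelled_by_unit_sum_weights(self):
        f = np.full(200, 3.0)
        w = np.array([0.5, 0.3, 0.2])
        p = prediction_error_filter(f, w)
        np.testing.assert_allclose(p[10:], 0.0, atol=1e-12)

    def test_matches_naive_convolution(self, rng):
        f = rng.standard_normal(500)
        w = rng.standard_normal(20)
        p = prediction_error_filter(f, w)
        naive = np.array(
            [f[t] - sum(w[i - 1] * f[t - i] for i in range(1, 21) if t - i >= 0)
             for t in range(500)]
        )
        np.testing.assert_allclose(p, naive, atol=1e-12)


class TestTheoreticalGain:
    def test_zero_weights_gain_is_one(self):
        assert theoretical_gain(EnsembleParams(0.5, 2.0), np.zeros(3)) == pytest.approx(
            1.0, rel=1e-6
        )

    def test_pure_noise_optimal_gain_is_one(self):
        params = EnsembleParams(0.5, 0.0)
        w = optimal_weights(0.5, 0.0, 10)
        assert theoretical_gain(params, w) == pytest.approx(1.0, rel=1e-9)
        assert theoretical_gain_closed_form(params) == pytest.approx(1.0, rel=1e-12)

    def test_numerical_integration_matches_closed_form(self):
        for beta, sigma in [(0.3, 0.1), (0.6, 1.0), (0.9, 10.0)]:
            params = EnsembleParams(beta, sigma)
            w = optimal_solution(beta, sigma).weights
            assert theoretical_gain(params, w) == pytest.approx(
                theoretical_gain_closed_form(params), rel=1e-6
            )

    def test_monte_carlo_oracle(self):
        beta, sigma = 0.5, 10.0
        params = EnsembleParams(beta, sigma)
        w = optimal_solution(beta, sigma).weights
        f = simulate_ensemble(beta, sigma, 10**6, seed=8)
        p = prediction_error_filter(f, w)
        emp = float(np.sum(p**2) / np.sum(f**2))
        assert emp == pytest.approx(theoretical_gain(params, w), rel=0.01)

    def test_local_optimality_of_closed_form(self, rng):
        params = EnsembleParams(0.6, 2.0)
        w = optimal_solution(0.6, 2.0).weights
        g_opt = theoretical_gain(params, w)
        for _ in range(10):
            perturbed = w + 0.05 * rng.standard_normal(w.size)
            assert theoretical_gain(params, perturbed) >= g_opt - 1e-12


class TestOutputSpectrum:
    def test_zero_weights_returns_input_spectrum(self):
        params = EnsembleParams(0.7, 3.0)
        freqs = np.linspace(0, 0.5, 100)
        np.testing.assert_allclose(
            output_spectrum(params, np.zeros(4), freqs),
            input_power_spectrum(params, freqs),
        )

    def test_nonnegative_everywhere(self, rng):
        params = EnsembleParams(0.7, 3.0)
        freqs = np.linspace(0, 0.5, 200)
        for _ in range(5):
            w = rng.standard_normal(8)
            assert np.all(output_spectrum(params, w, freqs) >= 0)

    def test_high_snr_whitening(self):
        # With near-pure signal the optimal filter flattens the output
        # spectrum: max/min ratio approaches 1 as sigma grows.
        freqs = np.linspace(0.0, 0.5, 200)
        for sigma, tol in [(100.0, 1.2), (1e4, 1.02)]:
            sol = optimal_solution(0.8, sigma)
            spec = output_spectrum(EnsembleParams(0.8, sigma), sol.weights, freqs)
            assert spec.max() / spec.min() < tol

    def test_frequency_domain_bounds(self):
        with pytest.raises(ValueError):
            input_power_spectrum(EnsembleParams(0.5, 1.0), np.array([0.6]))
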