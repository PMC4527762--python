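"""Closed-form optimal linear predictive coding.

A linear predictive coder transmits the prediction error

    p_t = f_t - sum_{i>=1} w_i f_{t-i}

and the weights that minimize the transmitted power ("network gain") for an
input made of an exponentially correlated signal (per-step correlation
``beta = exp(-1/tau_s)``) plus white noise at power SNR ``sigma`` form a
geometric sequence

    w_i = Lambda/(1 - Lambda) * (beta (1 - Lambda))**i .

Equivalently, the optimal prediction-error filter has transfer function

    H(z) = (1 - beta z^-1) / (1 - eta z^-1),   eta = beta (1 - Lambda).

Minimizing the output power of this one-pole/one-zero filter against the
analytic input spectrum reduces to a quadratic in eta,

    beta eta^2 - [1 + beta^2 + sigma (1 - beta^2)] eta + beta = 0,

whose root inside the unit circle gives the optimum.  ``Lambda*`` rises
monotonically from 0 (pure noise: predict nothing) to 1 (pure signal:
full-strength prediction) as the SNR grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EnsembleParams",
    "OptimalSolution",
    "beta_of_tau",
    "lambda_star",
    "optimal_weights",
    "optimal_solution",
    "prediction_error_filter",
    "input_power_spectrum",
    "transfer_magnitude_squared",
    "theoretical_gain",
    "theoretical_gain_closed_form",
    "output_spectrum",
]


def beta_of_tau(tau_s: float) -> float:
    """Per-step correlation factor ``exp(-1/tau_s)`` of the signal component."""
    if not tau_s > 0:
        raise ValueError(f"tau_s must be positive, got {tau_s!r}")
    return math.exp(-1.0 / tau_s)


@dataclass(frozen=True)
class EnsembleParams:
    """The two numbers that characterize the stationary input ensemble."""

    beta: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must lie in (0, 1), got {self.beta!r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma!r}")

    @property
    def tau_s(self) -> float:
        """Correlation time constant implied by beta."""
        return -1.0 / math.log(self.beta)

    @classmethod
    def from_tau(cls, tau_s: float, sigma: float) -> "EnsembleParams":
        return cls(beta_of_tau(tau_s), sigma)


def lambda_star(beta: float, sigma: float) -> float:
    """Optimal prediction-strength parameter ``Lambda*`` in [0, 1).

    ``Lambda* = 1 - eta/beta`` where ``eta`` is the stable root of the
    optimality quadratic (see module docstring). Evaluated in the
    cancellation-free form ``eta = 2 beta / (b + sqrt(b^2 - 4 beta^2))``
    with ``b = 1 + beta^2 + sigma (1 - beta^2)``, which is numerically
    stable for arbitrarily large sigma. ``sigma = inf`` returns the limit 1.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must lie in (0, 1), got {beta!r}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma!r}")
    if math.isinf(sigma):
        return 1.0
    b = 1.0 + beta * beta + sigma * (1.0 - beta * beta)
    eta = 2.0 * beta / (b + math.sqrt(b * b - 4.0 * beta * beta))
    lam = 1.0 - eta / beta
    # Clamp round-off at the sigma -> 0 end, where eta -> beta exactly.
    return min(max(lam, 0.0), 1.0)


def optimal_weights(beta: float, sigma: float, N: int) -> np.ndarray:
    """First ``N`` optimal prediction weights ``w_1 .. w_N``.

    The sequence is geometric: consecutive weights are in the exact ratio
    ``beta * (1 - Lambda*)``.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N!r}")
    lam = lambda_star(beta, sigma)
    eta = beta * (1.0 - lam)
    if lam == 0.0:
        return np.zeros(N)
    prefactor = lam / (1.0 - lam) if lam < 1.0 else None
    if prefactor is None:
        # sigma = inf limit: w_i = beta * [i == 1].
        w = np.zeros(N)
        w[0] = beta
        return w
    return prefactor * eta ** np.arange(1, N + 1)


@dataclass(frozen=True)
class OptimalSolution:
    """Truncated optimal filter for one input ensemble."""

    params: EnsembleParams
    lambda_star: float
    weights: np.ndarray
    truncation_N: int
    truncation_tolerance: float


def optimal_solution(
    beta: float, sigma: float, tol: float = 1e-12, max_N: int = 10_000
) -> OptimalSolution:
    """Optimal weights truncated once the dropped geometric tail is < ``tol``.

    The tail after N terms has l1 mass ``w_N * r / (1 - r)`` with ratio
    ``r = beta (1 - Lambda*)``; N is the smallest length pushing that mass
    below ``tol``.
    """
    lam = lambda_star(beta, sigma)
    r = beta * (1.0 - lam)
    if lam == 0.0 or r == 0.0:
        N = 1
    else:
        w1 = lam / (1.0 - lam) * r if lam < 1.0 else beta
        # w1 * r^(N-1) * r/(1-r) < tol  =>  N > 1 + log(tol(1-r)/(w1 r))/log r
        target = tol * (1.0 - r) / (w1 * r)
        N = 1 + max(0, math.ceil(math.log(target) / math.log(r)))
        N = min(N, max_N)
    return OptimalSolution(
        params=EnsembleParams(beta, sigma),
        lambda_star=lam,
        weights=optimal_weights(beta, sigma, N),
        truncation_N=N,
        truncation_tolerance=tol,
    )


def prediction_error_filter(f: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Apply ``p_t = f_t - sum_i w_i f_{t-i}`` with causal zero padding.

    Samples before t = 0 are treated as zero, so the first ``len(weights)``
    outputs carry an onset transient; stationary analyses should discard a
    burn-in.
    """
    f = np.asarray(f, dtype=float)
    if f.size == 0:
        raise ValueError("input series is empty")
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        return f.copy()
    kernel = np.concatenate(([1.0], -weights))
    return np.convolve(f, kernel)[: f.size]


def input_power_spectrum(params: EnsembleParams, freqs: np.ndarray) -> np.ndarray:
    """Analytic power spectral density of the signal+noise mixture.

    Frequencies are in cycles/step on [0, 0.5] (unit time step). The
    spectrum integrates to the total input power of 1: an AR(1) line
    spectrum ``(1-beta^2)/|1 - beta e^{-i 2 pi nu}|^2`` weighted by
    ``sigma/(1+sigma)`` plus a flat noise floor weighted by ``1/(1+sigma)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or np.any(freqs > 0.5):
        raise ValueError("frequencies must lie in [0, 0.5] cycles/step")
    beta, sigma = params.beta, params.sigma
    omega = 2.0 * np.pi * freqs
    ar1 = (1.0 - beta**2) / (1.0 + beta**2 - 2.0 * beta * np.cos(omega))
    if math.isinf(sigma):
        return ar1
    w_sig = sigma / (1.0 + sigma)
    return w_sig * ar1 + (1.0 - w_sig)


def transfer_magnitude_squared(weights: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """|H(e^{-i 2 pi nu})|^2 for the filter ``1 - sum_i w_i z^-i``."""
    weights = np.asarray(weights, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    i_lags = np.arange(1, weights.size + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, i_lags))
    H = 1.0 - phase @ weights if weights.size else np.ones(freqs.shape, complex)
    return np.abs(H) ** 2


def theoretical_gain(
    params: EnsembleParams, weights: np.ndarray, n_freq: int = 4096
) -> float:
    """Expected network gain of a weight vector on the analytic spectrum.

    Integrates ``|H|^2 S_f`` over frequency (two-sided symmetry folded onto
    [0, 0.5]) with the trapezoid rule; the input power normalization is 1 by
    construction, so the integral itself is the gain.
    """
    freqs = np.linspace(0.0, 0.5, n_freq)
    spectrum = input_power_spectrum(params, freqs) * transfer_magnitude_squared(
        weights, freqs
    )
    return float(2.0 * np.trapezoid(spectrum, freqs))


def theoretical_gain_closed_form(params: EnsembleParams) -> float:
    """Network gain of the untruncated optimal filter, in closed form.

    With ``eta = beta (1 - Lambda*)`` the optimal one-pole/one-zero filter
    achieves gain ``[sigma (1-beta^2) + (beta-eta)^2] / [(1+sigma)(1-eta^2)]
    + 1/(1+sigma)``; at ``sigma = 0`` this is exactly 1 (transmit the noise
    unmodified) and it decreases toward ``1 - beta^2`` as ``sigma`` grows.
    """
    beta, sigma = params.beta, params.sigma
    lam = lambda_star(beta, sigma)
    eta = beta * (1.0 - lam)
    if math.isinf(sigma):
        return 1.0 - beta * beta
    num = sigma * (1.0 - beta * beta) + (beta - eta) ** 2
    return num / ((1.0 + sigma) * (1.0 - eta * eta)) + 1.0 / (1.0 + sigma)


def output_spectrum(
    params: EnsembleParams, weights: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """Transmitted power spectrum: input spectrum times ``|H|^2``.

    With the optimal weights at high SNR the product flattens (whitening):
    the filter's gain is the reciprocal of the colored part of the input.
    """
    return input_power_spectrum(params, freqs) * transfer_magnitude_squared(
        weights, freqs
    )
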