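"""Linear leaky-integrator neurons and two-neuron predictive-coding circuits.

A leaky integrator discounts its past input by ``exp(-1/tau_m)`` per step —
a causal exponential low-pass filter. Two such neurons wired as a principal
cell plus an inhibitory interneuron implement linear predictive coding in
either of two arrangements:

* feedforward inhibition — the interneuron sees the *input*:
  ``n_t = alpha_hat (n_{t-1} + gamma_hat f_{t-1})``, ``p_t = f_t - n_t``;
* feedback inhibition — the interneuron sees the *transmitted output*:
  ``n_t = alpha (n_{t-1} + gamma p_{t-1})``, ``p_t = f_t - n_t``.

Both expand to geometric convolution filters, and both can realize the
optimal prediction-error filter for an exponentially correlated signal in
noise. The parameter mappings differ in a way that matters biologically: as
the input SNR varies, the feedforward circuit must retune the interneuron's
time constant, while the feedback circuit keeps ``alpha = beta`` fixed and
varies only the loop gain ``gamma = Lambda*``.

Because the transmitted series together with the circuit parameters
determines the prediction exactly, the input can always be reconstructed
losslessly from the output (predictive coding is a lossless code).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .linear_theory import lambda_star

__all__ = [
    "LeakyIntegrator",
    "FeedforwardParams",
    "FeedbackParams",
    "Trace",
    "leaky_filter",
    "simulate_feedforward",
    "simulate_feedback",
    "optimal_feedforward_params",
    "optimal_feedback_params",
    "reconstruct_input",
]


@dataclass(frozen=True)
class LeakyIntegrator:
    """Single-compartment RC neuron in discrete time.

    ``tau_m`` is the membrane time constant (in time steps) and ``g_s`` the
    synaptic conductance as a fraction of the membrane conductance. The
    voltage is ``v_t = (g_s/tau_m) sum_{i>=0} exp(-i/tau_m) input_{t-i}``;
    ``tau_m = 0`` degenerates to the memoryless response ``v_t = g_s input_t``.
    """

    tau_m: float
    g_s: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_m < 0:
            raise ValueError(f"tau_m must be >= 0, got {self.tau_m!r}")
        if not self.g_s > 0:
            raise ValueError(f"g_s must be positive, got {self.g_s!r}")

    @property
    def discount(self) -> float:
        """Per-step voltage discount ``exp(-1/tau_m)`` (0 for tau_m = 0)."""
        return 0.0 if self.tau_m == 0 else math.exp(-1.0 / self.tau_m)


@dataclass(frozen=True)
class FeedforwardParams:
    """Interneuron discount ``alpha_hat`` and feedforward gain ``gamma_hat``."""

    alpha_hat: float
    gamma_hat: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_hat < 1.0:
            raise ValueError(f"alpha_hat must lie in [0, 1), got {self.alpha_hat!r}")
        if self.gamma_hat < 0:
            raise ValueError(f"gamma_hat must be >= 0, got {self.gamma_hat!r}")


@dataclass(frozen=True)
class FeedbackParams:
    """Interneuron discount ``alpha`` and feedback loop gain ``gamma``.

    Stability of the expanded recursion requires ``alpha (1 - gamma) < 1``,
    automatic for ``alpha in [0, 1)`` and ``gamma in [0, 1]``.
    """

    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha!r}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma!r}")
        if self.eta >= 1.0:
            raise ValueError(
                f"alpha*(1-gamma) = {self.eta} >= 1: feedback recursion diverges"
            )

    @property
    def eta(self) -> float:
        """Effective geometric ratio ``alpha (1 - gamma)`` of the expanded filter."""
        return self.alpha * (1.0 - self.gamma)


@dataclass(frozen=True)
class Trace:
    """Aligned input / interneuron / principal-cell series from one run."""

    f: np.ndarray
    n: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        if not (self.f.shape == self.n.shape == self.p.shape):
            raise ValueError("f, n, p must have identical shapes")

    def as_columns(self) -> np.ndarray:
        """(T, 4) array of (t, f, n, p), ready for delimited-text output."""
        t = np.arange(self.f.size)
        return np.column_stack([t, self.f, self.n, self.p])


def leaky_filter(inputs: np.ndarray, neuron: LeakyIntegrator) -> np.ndarray:
    """Exponential low-pass response of a leaky integrator (causal, zero-padded)."""
    x = np.asarray(inputs, dtype=float)
    if neuron.tau_m == 0:
        return neuron.g_s * x
    d = neuron.discount
    scale = neuron.g_s / neuron.tau_m
    return scale * lfilter([1.0], [1.0, -d], x)


def simulate_feedforward(f: np.ndarray, params: FeedforwardParams) -> Trace:
    """Run the feedforward inhibitory circuit from a quiescent start (n_0 = 0).

    The one-step synaptic delay sits on the interneuron's input; expanding
    the recursion gives ``p_t = f_t - gamma_hat sum_{i>=1} alpha_hat^i f_{t-i}``.
    """
    f = np.asarray(f, dtype=float)
    a, g = params.alpha_hat, params.gamma_hat
    # n_t = a n_{t-1} + a g f_{t-1}
    n = lfilter([0.0, a * g], [1.0, -a], f)
    return Trace(f=f, n=n, p=f - n)


def simulate_feedback(f: np.ndarray, params: FeedbackParams) -> Trace:
    """Run the feedback inhibitory circuit from a quiescent start (n_0 = 0).

    Substituting ``p_{t-1} = f_{t-1} - n_{t-1}`` turns the pair of recursions
    into ``n_t = alpha(1-gamma) n_{t-1} + alpha gamma f_{t-1}``, which expands
    to ``p_t = f_t - gamma/(1-gamma) sum_{i>=1} (alpha(1-gamma))^i f_{t-i}``.
    """
    f = np.asarray(f, dtype=float)
    a, g = params.alpha, params.gamma
    n = lfilter([0.0, a * g], [1.0, -params.eta], f)
    return Trace(f=f, n=n, p=f - n)


def optimal_feedforward_params(beta: float, sigma: float) -> FeedforwardParams:
    """Feedforward parameters realizing the optimal prediction-error filter.

    ``alpha_hat = beta (1 - Lambda*)`` and ``gamma_hat = Lambda*/(1 - Lambda*)``:
    with rising SNR the gain grows without bound while the interneuron must
    get ever faster.
    """
    lam = lambda_star(beta, sigma)
    if lam >= 1.0:
        raise ValueError(
            "sigma = inf gives Lambda* = 1: the feedforward gain is unbounded"
        )
    return FeedforwardParams(alpha_hat=beta * (1.0 - lam), gamma_hat=lam / (1.0 - lam))


def optimal_feedback_params(beta: float, sigma: float) -> FeedbackParams:
    """Feedback parameters realizing the optimal prediction-error filter.

    ``alpha = beta`` (matched to the signal correlation, SNR-independent)
    and ``gamma = Lambda*``; only the loop gain adapts as the SNR changes.
    """
    return FeedbackParams(alpha=beta, gamma=lambda_star(beta, sigma))


def _decode_feedback(p: np.ndarray, params: FeedbackParams) -> np.ndarray:
    # The feedback prediction depends only on past *transmitted* values, so
    # the decoder rebuilds n directly from p: n_t = alpha n_{t-1} + alpha gamma p_{t-1}.
    a, g = params.alpha, params.gamma
    n = lfilter([0.0, a * g], [1.0, -a], p)
    return p + n


def _decode_feedforward(p: np.ndarray, params: FeedforwardParams) -> np.ndarray:
    # f_t = p_t + n_t with n built from reconstructed inputs. Eliminating f
    # gives a recursion in p alone: n_t = a(1+g) n_{t-1} + a g p_{t-1}.
    a, g = params.alpha_hat, params.gamma_hat
    n = lfilter([0.0, a * g], [1.0, -a * (1.0 + g)], p)
    return p + n


def _decode_weights(p: np.ndarray, weights: np.ndarray) -> np.ndarray:
    # Invert p_t = f_t - sum w_i f_{t-i} sequentially: the inverse of an FIR
    # prediction-error filter is the all-pole filter 1 / (1 - sum w_i z^-i).
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        return p.copy()
    return lfilter([1.0], np.concatenate(([1.0], -w)), p)


def reconstruct_input(
    p: np.ndarray, params: FeedbackParams | FeedforwardParams | np.ndarray
) -> np.ndarray:
    """Losslessly reconstruct the input from a transmitted series.

    Requires exact knowledge of the encoder (circuit parameters or weight
    vector) and of the quiescent initial state; under those conditions the
    round-trip error is at floating-point round-off level. One caveat for
    the feedforward form: its decoder recursion has pole
    ``alpha_hat (1 + gamma_hat)``, so round-off grows exponentially when
    that product reaches 1 (a non-minimum-phase encoder). The optimal
    mapping always gives ``alpha_hat (1 + gamma_hat) = beta < 1``.
    """
    p = np.asarray(p, dtype=float)
    if isinstance(params, FeedbackParams):
        return _decode_feedback(p, params)
    if isinstance(params, FeedforwardParams):
        return _decode_feedforward(p, params)
    return _decode_weights(p, np.asarray(params))
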