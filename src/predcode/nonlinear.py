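"""Dead-zone feedback circuits and describing-function analysis.

The linear feedback circuit needs its loop gain retuned whenever the input
SNR changes. Passing the interneuron's output through a *dead-zone*
(rectilinear) nonlinearity — zero within ``[-delta, +delta]``, unit slope
outside — removes that need: the interneuron integrates correlated input to
large amplitudes (a biased random walk) and rides above the threshold, so
the feedback is felt at nearly full strength; uncorrelated input keeps the
interneuron small and the feedback silent. The circuit therefore behaves
like a loop-gain-1 predictive coder on predictable input and a gain-0 coder
(transmit as-is) on unpredictable input, with no parameter changes.

Frequency-domain behavior is analyzed with the describing-function
(harmonic-balance) approximation standard in control theory: for a
sinusoidal drive, the nonlinearity is replaced by its first-harmonic
equivalent gain, solved self-consistently around the loop. Higher harmonics
are discarded by construction, so the resulting Bode curves are
qualitatively, not exactly, correct.

An extended three-neuron variant (upstream low-pass -> principal cell ->
interneuron, all with nonzero time constants) produces the smoothly rising,
biphasic temporal filters seen in sensory neurons and is the model used for
comparisons with reverse-correlation experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .circuits import FeedbackParams, Trace

__all__ = [
    "DeadZone",
    "NonlinearFeedbackParams",
    "ExtendedCircuitParams",
    "DescribingFunctionResult",
    "dead_zone",
    "simulate_nonlinear_feedback",
    "simulate_extended_circuit",
    "dead_zone_describing_gain",
    "linear_gain_curve",
    "nonlinear_bode",
    "measured_sinusoid_gain",
]


def dead_zone(x, delta: float):
    """Odd, piecewise-linear rectifier with threshold ``delta``.

    Returns ``x + delta`` for ``x < -delta``, 0 on ``[-delta, delta]`` and
    ``x - delta`` for ``x > delta``; ``delta = 0`` is the identity.
    """
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta!r}")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - delta, 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DeadZone:
    """Dead-zone nonlinearity with threshold ``delta``."""

    delta: float

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta!r}")

    def __call__(self, x):
        return dead_zone(x, self.delta)


@dataclass(frozen=True)
class NonlinearFeedbackParams:
    """Feedback circuit parameters plus rectification threshold.

    ``delta = 0`` reduces the circuit exactly to ``FeedbackParams(alpha, gamma)``.
    """

    alpha: float
    gamma: float
    delta: float

    def __post_init__(self) -> None:
        # Reuse the linear-circuit validation for (alpha, gamma).
        FeedbackParams(self.alpha, self.gamma)
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta!r}")

    @property
    def linear(self) -> FeedbackParams:
        return FeedbackParams(self.alpha, self.gamma)


@dataclass(frozen=True)
class ExtendedCircuitParams:
    """Three-neuron nonlinear circuit with nonzero time constants everywhere.

    ``tau_u`` is the upstream (input low-pass) neuron's time constant,
    ``tau_p`` the principal cell's, ``tau_i`` the interneuron's; ``gamma``
    and ``delta`` are the feedback gain and rectification threshold. Each
    low-pass stage is normalized to unit DC gain so responses are comparable
    across time constants. The analytic filter-shift result assumes the
    interneuron is slower than the principal cell (``tau_i > tau_p``).
    """

    tau_u: float = 5.0
    tau_p: float = 3.0
    tau_i: float = 12.0
    gamma: float = 0.9
    delta: float = 0.5

    def __post_init__(self) -> None:
        for name in ("tau_u", "tau_p", "tau_i"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.tau_i > self.tau_p:
            raise ValueError(
                f"tau_i ({self.tau_i}) must exceed tau_p ({self.tau_p}): the "
                "interneuron must be slower than the principal cell"
            )
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma!r}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta!r}")

    @property
    def discounts(self) -> tuple[float, float, float]:
        """Per-step discounts (a_u, a_p, a_i); a tau of 0 gives discount 0."""
        return tuple(
            0.0 if tau == 0 else math.exp(-1.0 / tau)
            for tau in (self.tau_u, self.tau_p, self.tau_i)
        )


# ---------------------------------------------------------------------------
# Time-domain simulators. The cores broadcast over arbitrary leading axes so
# that trials (and, in the evaluation module, parameter grids) run in one
# vectorized time loop.
# ---------------------------------------------------------------------------


def _nl_feedback_paths(F, alpha, gamma, delta):
    """Batched nonlinear feedback recursion.

    ``F`` has shape (..., T); ``alpha``, ``gamma``, ``delta`` broadcast
    against ``F[..., 0]``. The interneuron integrates its *raw* state; the
    rectifier applies to its output as seen by the principal cell:
    ``n_t = alpha (n_{t-1} + gamma p_{t-1})``, ``p_t = f_t - R_delta(n_t)``.
    Returns (N, P) with the same shape as F.
    """
    F = np.asarray(F, dtype=float)
    T = F.shape[-1]
    batch = np.broadcast_shapes(
        F[..., 0].shape, np.shape(alpha), np.shape(gamma), np.shape(delta)
    )
    alpha = np.broadcast_to(np.asarray(alpha, float), batch)
    gamma = np.broadcast_to(np.asarray(gamma, float), batch)
    delta = np.broadcast_to(np.asarray(delta, float), batch)
    N = np.empty(batch + (T,))
    P = np.empty(batch + (T,))
    n = np.zeros(batch)
    p_prev = np.zeros(batch)
    for t in range(T):
        n = alpha * (n + gamma * p_prev)
        fed = np.sign(n) * np.maximum(np.abs(n) - delta, 0.0)
        p_prev = F[..., t] - fed
        N[..., t] = n
        P[..., t] = p_prev
    return N, P


def simulate_nonlinear_feedback(f: np.ndarray, params: NonlinearFeedbackParams) -> Trace:
    """Run the dead-zone feedback circuit from a quiescent start."""
    f = np.asarray(f, dtype=float)
    n, p = _nl_feedback_paths(f, params.alpha, params.gamma, params.delta)
    return Trace(f=f, n=n, p=p)


def _extended_paths(F, a_u, a_p, a_i, gamma, delta):
    """Batched three-neuron recursion (unit-DC-gain low-pass stages).

    u_t = a_u u_{t-1} + (1-a_u) f_t
    n_t = a_i n_{t-1} + (1-a_i) gamma p_{t-1}
    p_t = a_p p_{t-1} + (1-a_p) (u_t - R_delta(n_t))
    """
    F = np.asarray(F, dtype=float)
    T = F.shape[-1]
    batch = np.broadcast_shapes(F[..., 0].shape, np.shape(delta))
    delta = np.broadcast_to(np.asarray(delta, float), batch)
    N = np.empty(batch + (T,))
    P = np.empty(batch + (T,))
    u = np.zeros(batch)
    n = np.zeros(batch)
    p = np.zeros(batch)
    for t in range(T):
        u = a_u * u + (1.0 - a_u) * F[..., t]
        n = a_i * n + (1.0 - a_i) * gamma * p
        fed = np.sign(n) * np.maximum(np.abs(n) - delta, 0.0)
        p = a_p * p + (1.0 - a_p) * (u - fed)
        N[..., t] = n
        P[..., t] = p
    return N, P


def simulate_extended_circuit(f: np.ndarray, params: ExtendedCircuitParams) -> Trace:
    """Run the three-neuron nonlinear circuit from a quiescent start.

    With all three time constants nonzero the linearized impulse response
    has near-zero weight at lag 0, rises to a peak and then dips to a
    trough — the biphasic shape of measured sensory filters. As
    ``delta -> inf`` the feedback never engages and the circuit degenerates
    to a cascade of two low-pass filters.
    """
    f = np.asarray(f, dtype=float)
    a_u, a_p, a_i = params.discounts
    n, p = _extended_paths(f, a_u, a_p, a_i, params.gamma, params.delta)
    return Trace(f=f, n=n, p=p)


# ---------------------------------------------------------------------------
# Describing-function (harmonic-balance) analysis
# ---------------------------------------------------------------------------


def dead_zone_describing_gain(A: float, delta: float) -> float:
    """First-harmonic equivalent gain of the dead zone for a sinusoid.

    The fundamental Fourier coefficient of ``R_delta(A sin theta)`` divided
    by ``A``, computed by quadrature. Zero for ``A <= delta``, monotone
    increasing in ``A``, approaching 1 as ``A/delta -> inf``; ``delta = 0``
    gives exactly 1 (identity).
    """
    if not A > 0:
        raise ValueError(f"A must be positive, got {A!r}")
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta!r}")
    if delta == 0.0:
        return 1.0
    if A <= delta:
        return 0.0
    integrand = lambda th: dead_zone(A * math.sin(th), delta) * math.sin(th)
    # The integrand has kinks where A sin(theta) crosses the threshold;
    # splitting there keeps the quadrature at full accuracy.
    th0 = math.asin(delta / A)
    val, _ = quad(integrand, 0.0, math.pi, points=[th0, math.pi - th0], limit=200)
    # b1 = (2/pi) * integral over half period; equivalent gain = b1 / A.
    return float((2.0 / math.pi) * val / A)


@dataclass(frozen=True)
class DescribingFunctionResult:
    """Harmonic-balance solution of the nonlinear loop on a frequency grid."""

    frequencies: np.ndarray
    input_amplitude: float
    equivalent_gain: np.ndarray
    network_gain: np.ndarray
    converged: np.ndarray

    def as_columns(self) -> np.ndarray:
        return np.column_stack(
            [self.frequencies, self.equivalent_gain, self.network_gain]
        )


def _loop_transfers(alpha: float, gamma: float, k, omega):
    """Transfer functions of the gain-k-linearized loop at angular freq omega.

    With the rectifier replaced by equivalent gain k, the loop is linear:
    H_p = (1 - alpha z^-1)/(1 - alpha(1 - k gamma) z^-1) maps input to
    principal output, H_n = alpha gamma z^-1/(1 - alpha(1 - k gamma) z^-1)
    maps input to interneuron state.
    """
    z1 = np.exp(-1j * np.asarray(omega))
    denom = 1.0 - alpha * (1.0 - np.asarray(k) * gamma) * z1
    H_p = (1.0 - alpha * z1) / denom
    H_n = alpha * gamma * z1 / denom
    return H_p, H_n


def linear_gain_curve(alpha: float, gamma: float, frequencies: np.ndarray) -> np.ndarray:
    """Network-gain Bode curve ``|H_p|^2`` of the *linear* feedback circuit.

    ``gamma = 0`` is identically 1 (transmit unchanged); ``gamma = 1``
    attenuates low frequencies and amplifies those near Nyquist (whitening).
    """
    omega = 2.0 * np.pi * np.asarray(frequencies, dtype=float)
    # The linear circuit is the k = 1 member of the linearized-loop family.
    H_p, _ = _loop_transfers(alpha, gamma, 1.0, omega)
    return np.abs(H_p) ** 2


def nonlinear_bode(
    params: NonlinearFeedbackParams,
    frequencies: np.ndarray,
    amplitude: float,
    tol: float = 1e-8,
    max_iter: int = 1000,
    damping: float = 0.5,
) -> DescribingFunctionResult:
    """Describing-function Bode analysis of the dead-zone feedback loop.

    Per frequency, solves the fixed point ``k = N_df(|H_n(k)| A)`` for the
    rectifier's first-harmonic equivalent gain ``k`` by damped iteration,
    then reports the resulting network gain ``|H_p(k)|^2``. Frequencies are
    in cycles/step on (0, 0.5]. Non-convergent frequencies are flagged in
    ``converged`` rather than raising.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs > 0.5):
        raise ValueError("frequencies must lie in (0, 0.5] cycles/step")
    if not amplitude > 0:
        raise ValueError(f"amplitude must be positive, got {amplitude!r}")
    alpha, gamma, delta = params.alpha, params.gamma, params.delta
    k_out = np.empty(freqs.size)
    gain_out = np.empty(freqs.size)
    ok = np.empty(freqs.size, dtype=bool)
    def balance_residual(k: float, omega: float) -> float:
        _, H_n = _loop_transfers(alpha, gamma, k, omega)
        A_n = float(np.abs(H_n)) * amplitude
        k_new = dead_zone_describing_gain(A_n, delta) if A_n > 0 else 0.0
        return k_new - k

    for j, nu in enumerate(freqs):
        omega = 2.0 * math.pi * nu
        k = 0.5
        converged = False
        for _ in range(max_iter):
            step = balance_residual(k, omega)
            k = k + damping * step
            if abs(step) < tol * max(1.0, abs(k)):
                converged = True
                break
        if not converged:
            # The residual is continuous with opposite signs at k = 0 and
            # k = 1 (the equivalent gain lies in [0, 1]), so a bracketing
            # root-finder recovers a fixed point the iteration missed.
            from scipy.optimize import brentq

            try:
                k = float(brentq(lambda kk: balance_residual(kk, omega), 0.0, 1.0,
                                 xtol=1e-12))
                converged = abs(balance_residual(k, omega)) < 10 * tol
            except ValueError:
                pass
        H_p, _ = _loop_transfers(alpha, gamma, k, omega)
        k_out[j] = k
        gain_out[j] = float(np.abs(H_p)) ** 2
        ok[j] = converged
    return DescribingFunctionResult(
        frequencies=freqs,
        input_amplitude=float(amplitude),
        equivalent_gain=k_out,
        network_gain=gain_out,
        converged=ok,
    )


def measured_sinusoid_gain(
    params: NonlinearFeedbackParams,
    frequency: float,
    amplitude: float,
    n_samples: int = 8192,
    burn_in: int = 2048,
) -> float:
    """First-harmonic network gain measured from a time-domain simulation.

    Drives the full nonlinear circuit with ``A sin(2 pi nu t)``, discards a
    burn-in, and projects input and output onto the drive frequency; the
    returned power ratio is the time-domain analog of the
    describing-function gain (higher harmonics are excluded the same way).
    """
    if not 0.0 < frequency <= 0.5:
        raise ValueError("frequency must lie in (0, 0.5] cycles/step")
    t = np.arange(n_samples)
    f = amplitude * np.sin(2.0 * np.pi * frequency * t)
    trace = simulate_nonlinear_feedback(f, params)
    # Window an integer number of periods to avoid spectral leakage.
    period = 1.0 / frequency
    n_avail = n_samples - burn_in
    window = int(math.floor(n_avail / period) * period) or n_avail
    sl = slice(n_samples - window, n_samples)
    phasor = np.exp(-2j * np.pi * frequency * t[sl])
    c_p = np.sum(trace.p[sl] * phasor)
    c_f = np.sum(f[sl] * phasor)
    return float(np.abs(c_p / c_f) ** 2)
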