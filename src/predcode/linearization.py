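"""Reverse-correlation estimates of the nonlinear circuit's effective filter.

A nonlinear circuit has no single impulse response, but its behavior at a
given input amplitude can be summarized by a linearized temporal filter
estimated exactly the way experimentalists do: drive the circuit with many
trials of Gaussian white noise, pick a late readout time, and average the
stimulus preceding the readout weighted by the (graded) output — a
spike-triggered average with the spike train replaced by the membrane
output. Because the stimulus is white, this average is proportional to the
best linear filter approximating the circuit at that amplitude.

The filters are then summarized by the three statistics used to compare
models with sensory recordings: the ratio of total positive to total
negative filter mass, the best mean frequency (BMF — the frequency of the
peak of the filter's Fourier transform), and the lag of the filter's
largest extremum. As the input amplitude grows, the dead-zone feedback
engages more strongly and the filter differentiates more: BMF rises, the
positive/negative ratio falls, and the extremum shifts toward the recent
past — the signature of fast contrast adaptation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nonlinear import (
    ExtendedCircuitParams,
    NonlinearFeedbackParams,
    _extended_paths,
    _nl_feedback_paths,
)

__all__ = [
    "LinearizedFilter",
    "FilterMetrics",
    "estimate_sta_filter",
    "pos_neg_ratio",
    "best_mean_frequency",
    "extremum_lag",
    "filter_metrics",
    "amplitude_sweep",
]


@dataclass(frozen=True)
class LinearizedFilter:
    """Reverse-correlation kernel of a circuit at one input amplitude.

    ``kernel[l]`` weights the input ``l`` steps before the readout time.
    """

    kernel: np.ndarray
    input_amplitude: float
    n_trials: int
    trial_length: int
    seed: int

    def __post_init__(self) -> None:
        if self.kernel.size >= self.trial_length:
            raise ValueError("number of lags must be smaller than trial_length")


@dataclass(frozen=True)
class FilterMetrics:
    """Summary statistics of a temporal filter."""

    pos_neg_ratio: float
    bmf: float
    extremum_lag: int


def _simulate_batch(circuit, F: np.ndarray) -> np.ndarray:
    """Output paths of either nonlinear circuit for stacked trials F."""
    if isinstance(circuit, ExtendedCircuitParams):
        a_u, a_p, a_i = circuit.discounts
        _, P = _extended_paths(F, a_u, a_p, a_i, circuit.gamma, circuit.delta)
    elif isinstance(circuit, NonlinearFeedbackParams):
        _, P = _nl_feedback_paths(F, circuit.alpha, circuit.gamma, circuit.delta)
    else:
        raise TypeError(f"unsupported circuit type: {type(circuit).__name__}")
    return P


def estimate_sta_filter(
    circuit: ExtendedCircuitParams | NonlinearFeedbackParams,
    amplitude: float,
    n_trials: int = 2000,
    trial_length: int = 1000,
    lags: int = 60,
    seed: int = 0,
) -> LinearizedFilter:
    """Estimate a linearized filter by output-weighted reverse correlation.

    Each trial is Gaussian white noise with standard deviation
    ``amplitude``. The readout is the final sample of each trial (by then
    the circuit state is stationary);
    ``kernel[l] = mean_trials(p[t*] * f[t* - l]) / amplitude**2``, so for a
    purely linear circuit the kernel equals its impulse response
    independent of amplitude.
    """
    if not amplitude > 0:
        raise ValueError(f"amplitude must be positive, got {amplitude!r}")
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials!r}")
    if lags >= trial_length:
        raise ValueError("lags must be smaller than trial_length")
    rng = np.random.default_rng(seed)
    F = amplitude * rng.standard_normal((n_trials, trial_length))
    P = _simulate_batch(circuit, F)
    readout = P[:, -1]
    lag_idx = trial_length - 1 - np.arange(lags)
    kernel = (readout[:, None] * F[:, lag_idx]).mean(axis=0) / amplitude**2
    return LinearizedFilter(
        kernel=kernel,
        input_amplitude=float(amplitude),
        n_trials=int(n_trials),
        trial_length=int(trial_length),
        seed=int(seed),
    )


def _kernel_of(filt: LinearizedFilter | np.ndarray) -> np.ndarray:
    k = filt.kernel if isinstance(filt, LinearizedFilter) else np.asarray(filt, float)
    if not np.any(k):
        raise ValueError("kernel is identically zero")
    return k


def pos_neg_ratio(filt: LinearizedFilter | np.ndarray) -> float:
    """Total positive filter mass over total negative mass.

    A filter with no negative lobe returns ``inf`` (pure integrator); the
    ratio shrinks as the filter becomes more differentiating.
    """
    k = _kernel_of(filt)
    pos = float(k[k > 0].sum())
    neg = float(-k[k < 0].sum())
    return math.inf if neg == 0.0 else pos / neg


def best_mean_frequency(filt: LinearizedFilter | np.ndarray, nfft: int = 4096) -> float:
    """Frequency (cycles/step) of the peak of the kernel's Fourier magnitude.

    The kernel is zero-padded to ``nfft`` for frequency resolution; the DC
    bin is excluded, so the result lies in (0, 0.5].
    """
    k = _kernel_of(filt)
    mag = np.abs(np.fft.rfft(k, n=nfft))
    freqs = np.fft.rfftfreq(nfft)
    j = 1 + int(np.argmax(mag[1:]))
    return float(freqs[j])


def extremum_lag(filt: LinearizedFilter | np.ndarray) -> int:
    """Lag of the largest-magnitude kernel value (ties -> smaller lag)."""
    k = _kernel_of(filt)
    return int(np.argmax(np.abs(k)))


def filter_metrics(filt: LinearizedFilter | np.ndarray) -> FilterMetrics:
    return FilterMetrics(
        pos_neg_ratio=pos_neg_ratio(filt),
        bmf=best_mean_frequency(filt),
        extremum_lag=extremum_lag(filt),
    )


def amplitude_sweep(
    circuit: ExtendedCircuitParams | NonlinearFeedbackParams,
    amplitudes: np.ndarray,
    n_trials: int = 2000,
    trial_length: int = 1000,
    lags: int = 60,
    seed: int = 0,
) -> list[tuple[LinearizedFilter, FilterMetrics]]:
    """Estimate filters and metrics across an input-amplitude sweep.

    The same seed (hence the same normalized noise) is reused at every
    amplitude, so the sweep isolates the amplitude dependence of the
    circuit from sampling noise.
    """
    out = []
    for a in np.asarray(amplitudes, dtype=float):
        filt = estimate_sta_filter(
            circuit, float(a), n_trials=n_trials, trial_length=trial_length,
            lags=lags, seed=seed,
        )
        out.append((filt, filter_metrics(filt)))
    return out
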