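"""Synthetic stimulus ensembles for predictive-coding experiments.

The circuits in this package are studied on a small family of discrete-time
stimuli:

* an exponentially correlated ("predictable") signal — a stationary AR(1)
  process whose autocorrelation decays as ``beta**i`` with
  ``beta = exp(-1/tau_s)``;
* uncorrelated ("unpredictable") Gaussian white noise;
* a deterministic alternating input at the Nyquist frequency, the highest
  representable discrete frequency and therefore unpredictable to any causal
  low-pass predictor;
* stationary mixtures of signal and noise at a prescribed power
  signal-to-noise ratio sigma;
* non-stationary two-segment mixtures that switch instantaneously from one
  pure component to another, emulating an abrupt change in input statistics
  (e.g. across a saccade).

All generators are seeded and bitwise reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "InputSpec",
    "Segment",
    "MixtureSpec",
    "gen_correlated_signal",
    "gen_white_noise",
    "gen_nyquist",
    "mix_snr",
    "gen_mixture",
]

SEGMENT_KINDS = ("signal", "white_noise", "nyquist")


def _validate_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class InputSpec:
    """Parameters of a stationary signal-plus-noise ensemble.

    Attributes
    ----------
    tau_s:
        Correlation time constant of the signal component, in time steps.
    sigma:
        Power SNR: ratio of signal power to noise power. May be ``inf``
        (pure signal) or 0 (pure noise).
    n:
        Series length.
    seed:
        Master seed for the generator.
    """

    tau_s: float
    sigma: float
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        _validate_positive("tau_s", self.tau_s)
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma!r}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n!r}")

    @property
    def beta(self) -> float:
        """Per-step correlation factor ``exp(-1/tau_s)``."""
        return math.exp(-1.0 / self.tau_s)

    def generate(self) -> np.ndarray:
        """Draw one realization ``f`` of the ensemble."""
        s = gen_correlated_signal(self.tau_s, self.n, self.seed)
        eps = gen_white_noise(self.n, 1.0, self.seed + 1)
        return mix_snr(s, eps, self.sigma)


@dataclass(frozen=True)
class Segment:
    """One homogeneous stretch of a non-stationary mixture."""

    kind: str
    amplitude: float
    length: int

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(
                f"unknown segment kind {self.kind!r}; expected one of {SEGMENT_KINDS}"
            )
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude!r}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length!r}")


@dataclass(frozen=True)
class MixtureSpec:
    """A non-stationary input built by concatenating pure segments.

    A "1:1 mixture" has exactly two segments of equal length; the canonical
    protocol uses a pure correlated-signal segment followed by a pure
    unpredictable segment (white noise or Nyquist input).
    """

    segments: tuple[Segment, ...]
    tau_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("MixtureSpec needs at least one segment")
        _validate_positive("tau_s", self.tau_s)
        # Normalize: accept plain tuples/lists for segments.
        segs = tuple(
            s if isinstance(s, Segment) else Segment(*s) for s in self.segments
        )
        object.__setattr__(self, "segments", segs)

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    # -- JSON round-trip ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "segments": [
                    {"kind": s.kind, "amplitude": s.amplitude, "length": s.length}
                    for s in self.segments
                ],
                "tau_s": self.tau_s,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MixtureSpec":
        obj = json.loads(text)
        segments = tuple(
            Segment(d["kind"], d["amplitude"], d["length"]) for d in obj["segments"]
        )
        return cls(segments=segments, tau_s=obj["tau_s"], seed=obj["seed"])


def gen_correlated_signal(tau_s: float, n: int, seed: int) -> np.ndarray:
    """Stationary, zero-mean, unit-variance exponentially correlated series.

    The process is AR(1): ``s_t = beta * s_{t-1} + sqrt(1 - beta**2) * xi_t``
    with ``beta = exp(-1/tau_s)`` and Gaussian innovations. ``s_0`` is drawn
    from the stationary distribution so the autocorrelation equals
    ``beta**i`` at every lag from the first sample on.
    """
    _validate_positive("tau_s", tau_s)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    beta = math.exp(-1.0 / tau_s)
    rng = np.random.default_rng(seed)
    s0 = rng.standard_normal()
    xi = rng.standard_normal(n - 1)
    if n == 1:
        return np.array([s0])
    # s[1:] = beta*s[:-1] + c*xi, seeded with the stationary draw s0.
    c = math.sqrt(1.0 - beta * beta)
    tail, _ = lfilter([c], [1.0, -beta], xi, zi=np.array([beta * s0]))
    return np.concatenate(([s0], tail))


def gen_white_noise(n: int, amplitude: float, seed: int) -> np.ndarray:
    """Zero-mean Gaussian white noise with standard deviation ``amplitude``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude!r}")
    rng = np.random.default_rng(seed)
    return amplitude * rng.standard_normal(n)


def gen_nyquist(n: int, amplitude: float) -> np.ndarray:
    """Deterministic alternation ``+A, -A, +A, ...`` at the Nyquist frequency.

    The phase convention starts at ``+amplitude`` at t = 0.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude!r}")
    out = np.empty(n)
    out[0::2] = amplitude
    out[1::2] = -amplitude
    return out


def mix_snr(s: np.ndarray, eps: np.ndarray, sigma: float) -> np.ndarray:
    """Combine signal and noise at power SNR ``sigma``.

    ``f = sqrt(sigma/(1+sigma)) * s + sqrt(1/(1+sigma)) * eps`` so that for
    unit-variance components the signal-to-noise power ratio is exactly
    ``sigma`` and the total power is 1. ``sigma = inf`` returns the pure
    signal component; ``sigma = 0`` the pure noise component.
    """
    s = np.asarray(s, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if s.shape != eps.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {eps.shape}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma!r}")
    if math.isinf(sigma):
        return s.copy()
    w_s = math.sqrt(sigma / (1.0 + sigma))
    w_e = math.sqrt(1.0 / (1.0 + sigma))
    return w_s * s + w_e * eps


def _segment_seed(master: int, index: int) -> int:
    """Deterministic per-segment sub-seed.

    Segment 0 inherits the master seed unchanged, so a single-segment
    mixture reproduces the bare generator call bit for bit. Later segments
    hash (master, index) through a SeedSequence to obtain independent
    streams.
    """
    if index == 0:
        return master
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0])


def gen_mixture(spec: MixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate the segments of ``spec`` into one series.

    Returns ``(f, labels)`` where ``labels[t]`` is the index of the segment
    that generated sample ``t``.
    """
    parts: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for i, seg in enumerate(spec.segments):
        seed = _segment_seed(spec.seed, i)
        if seg.kind == "signal":
            x = seg.amplitude * gen_correlated_signal(spec.tau_s, seg.length, seed)
        elif seg.kind == "white_noise":
            x = gen_white_noise(seg.length, seg.amplitude, seed)
        elif seg.kind == "nyquist":
            x = gen_nyquist(seg.length, seg.amplitude)
        else:  # pragma: no cover - guarded by Segment.__post_init__
            raise ValueError(f"unknown segment kind {seg.kind!r}")
        parts.append(x)
        labels.append(np.full(seg.length, i, dtype=np.intp))
    return np.concatenate(parts), np.concatenate(labels)
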