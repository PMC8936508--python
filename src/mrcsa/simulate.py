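"""Mixed-correlated ARFIMA pairs with known cross-spectral exponent.

An ARFIMA(0, d, 0) stream is the fractional integration of Gaussian
innovations, ``p_t = sum_n psi_n(d) eps_{t-n}`` with
``psi_n = Gamma(n+d) / (Gamma(n+1) Gamma(d))`` (``psi_0 = 1``); its Hurst
exponent is ``H = 0.5 + d``.  A mixed-correlated pair combines four such
streams,

    u_t = w1 * p1_t + w2 * p2_t,        v_t = w3 * p3_t + w4 * p4_t,

with jointly Gaussian innovations whose correlation matrix ``rho`` couples
streams 2 and 3.  With ``rho_23 > 0`` the pair is genuinely long-range
cross-correlated with bivariate Hurst exponent ``H_uv = (H2 + H3) / 2`` and
cross-spectral exponent ``beta_uv = 2 H_uv - 1 = d2 + d3``.

Correlated oscillations are modelled by adding the *same* unit-variance
sinusoid (one uniform-random phase per frequency) to both channels, its
variance set to ``rel_variance * f**(-beta_uv)`` so the peak stays in a fixed
proportion to the fractal cross-power at its frequency (f in Hz).
Measurement noise is independent white Gaussian noise per channel, with the
signal-to-noise ratio expressed as ``100 * var(signal) / var(noise)``
(percent); an SNR of 0 is the noise-free control.

The module also provides a shared-phase inverse-FFT power-law generator whose
theoretical cross-spectral exponent ``(beta_x + beta_y) / 2`` is exact by
construction — the test oracle for the separation and fitting code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import TimeSeriesPair, ValidationError

__all__ = [
    "McArfimaParams",
    "OscillationSpec",
    "NoiseSpec",
    "arfima_weights",
    "simulate_mc_arfima",
    "inject_oscillations",
    "add_white_noise",
    "synthesize_powerlaw_pair",
]

DEFAULT_N_WEIGHTS = 100


def _default_rho() -> np.ndarray:
    rho = np.eye(4)
    rho[1, 2] = rho[2, 1] = 0.9
    return rho


@dataclass(frozen=True)
class McArfimaParams:
    """Weights, memory parameters and innovation structure of the pair.

    Defaults follow the standard demonstration parameterization
    ``w1 = w4 = 0.1, w2 = w3 = 1, d = (0.4, 0.3, 0.2, 0.3)``, unit innovation
    variances and ``rho_23 = 0.9``, which yields ``beta_uv = 0.5``.
    """

    w: tuple[float, float, float, float] = (0.1, 1.0, 1.0, 0.1)
    d: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.3)
    sigma2: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    rho: np.ndarray = field(default_factory=_default_rho)
    n_weights: int = DEFAULT_N_WEIGHTS

    def __post_init__(self):
        if len(self.w) != 4 or len(self.d) != 4 or len(self.sigma2) != 4:
            raise ValidationError("w, d and sigma2 must each contain four entries")
        for di in self.d:
            if not 0 <= di < 0.5:
                raise ValidationError(f"memory parameters must lie in [0, 0.5), got {di}")
        if any(s <= 0 for s in self.sigma2):
            raise ValidationError("innovation variances must be positive")
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape != (4, 4) or not np.allclose(rho, rho.T):
            raise ValidationError("rho must be a symmetric 4x4 matrix")
        if not np.allclose(np.diag(rho), 1.0):
            raise ValidationError("rho must have a unit diagonal")
        if np.linalg.eigvalsh(rho).min() < -1e-10:
            raise ValidationError("rho must be positive semidefinite")
        if self.n_weights < 1:
            raise ValidationError("n_weights must be at least 1")
        object.__setattr__(self, "rho", rho)

    @property
    def beta_theoretical(self) -> float:
        """Cross-spectral exponent ``2 * (H2 + H3)/2 - 1 = d2 + d3``."""
        return self.d[1] + self.d[2]

    @classmethod
    def with_cross_exponent(cls, beta: float, **kwargs) -> "McArfimaParams":
        """Defaults adjusted so the coupled streams give ``beta_uv = beta``."""
        if not 0 <= beta < 1.0:
            raise ValidationError(f"beta must lie in [0, 1), got {beta}")
        d = (0.4, beta / 2, beta / 2, 0.3)
        return cls(d=d, **kwargs)


@dataclass(frozen=True)
class OscillationSpec:
    """A correlated sinusoid at ``freq`` Hz with variance ``rel_variance``
    (relative to unit signal variance, before the ``f**(-beta)`` adjustment)."""

    freq: float
    rel_variance: float
    phase: float | None = None

    def __post_init__(self):
        if not (math.isfinite(self.freq) and self.freq > 0):
            raise ValidationError(f"oscillation frequency must be positive, got {self.freq}")
        if not (math.isfinite(self.rel_variance) and self.rel_variance > 0):
            raise ValidationError(f"rel_variance must be positive, got {self.rel_variance}")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white noise level: ``snr_percent = 100 * var(signal)/var(noise)``."""

    snr_percent: float

    def __post_init__(self):
        if not (math.isfinite(self.snr_percent) and self.snr_percent >= 0):
            raise ValidationError(f"snr_percent must be nonnegative, got {self.snr_percent}")


def arfima_weights(d: float, n_max: int = DEFAULT_N_WEIGHTS) -> np.ndarray:
    """Fractional-integration weights ``psi_n`` for ``n = 0 .. n_max-1``.

    Computed by the stable recurrence ``psi_n = psi_{n-1} (n-1+d)/n`` with
    ``psi_0 = 1``; for ``d = 0`` the stream degenerates to white noise.
    """
    if not (isinstance(d, (int, float)) and math.isfinite(d) and 0 <= d < 0.5):
        raise ValidationError(f"memory parameter d must lie in [0, 0.5), got {d!r}")
    if n_max < 1:
        raise ValidationError(f"n_max must be at least 1, got {n_max}")
    psi = np.empty(n_max)
    psi[0] = 1.0
    for n in range(1, n_max):
        psi[n] = psi[n - 1] * (n - 1 + d) / n
    return psi


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def simulate_mc_arfima(
    params: McArfimaParams,
    n_samples: int = 10_000,
    fs: float = 500.0,
    seed: int | np.random.Generator = 0,
) -> TimeSeriesPair:
    """Draw one mixed-correlated ARFIMA pair, standardized per channel.

    Innovations are jointly Gaussian with correlation ``rho`` (via Cholesky
    factorization) and variances ``sigma2``; each stream is the truncated
    convolution with its weight sequence, and the first ``n_weights`` samples
    are discarded as burn-in.
    """
    if n_samples < 256:
        raise ValidationError(f"n_samples must be at least 256, got {n_samples}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    burn = params.n_weights
    total = n_samples + burn
    try:
        chol = np.linalg.cholesky(params.rho + 1e-12 * np.eye(4))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in __post_init__
        raise ValidationError("rho is not positive semidefinite") from exc
    eps = chol @ rng.standard_normal((4, total))
    eps *= np.sqrt(np.asarray(params.sigma2))[:, None]

    streams = []
    for i in range(4):
        psi = arfima_weights(params.d[i], params.n_weights)
        streams.append(np.convolve(eps[i], psi)[:total])
    u = params.w[0] * streams[0] + params.w[1] * streams[1]
    v = params.w[2] * streams[2] + params.w[3] * streams[3]
    return TimeSeriesPair(_standardize(u[burn:]), _standardize(v[burn:]), fs)


def inject_oscillations(
    pair: TimeSeriesPair,
    oscs: list[OscillationSpec],
    beta_uv: float,
    seed: int | np.random.Generator = 0,
) -> TimeSeriesPair:
    """Add the same scaled sinusoid(s) to both channels (fully correlated).

    Each sinusoid is standardized to unit variance and multiplied by
    ``sqrt(rel_variance * freq**(-beta_uv))``; one uniform phase is drawn per
    oscillation unless the spec fixes it.
    """
    if not oscs:
        return pair
    freqs = [o.freq for o in oscs]
    if len(set(freqs)) != len(freqs):
        raise ValidationError(f"duplicate oscillation frequencies: {freqs}")
    nyquist = pair.fs / 2
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(len(pair)) / pair.fs
    added = np.zeros(len(pair))
    for osc in oscs:
        if osc.freq >= nyquist:
            raise ValidationError(
                f"oscillation at {osc.freq} Hz is at or above the Nyquist rate {nyquist} Hz"
            )
        phase = rng.uniform(0, 2 * np.pi) if osc.phase is None else osc.phase
        wave = _standardize(np.sin(2 * np.pi * osc.freq * t + phase))
        added += wave * math.sqrt(osc.rel_variance * osc.freq ** (-beta_uv))
    return TimeSeriesPair(pair.x + added, pair.y + added, pair.fs)


def add_white_noise(
    pair: TimeSeriesPair,
    noise: NoiseSpec,
    seed: int | np.random.Generator = 0,
) -> TimeSeriesPair:
    """Add independent Gaussian noise per channel at the requested SNR.

    The added variance per channel is ``var(channel) * 100 / snr_percent``;
    ``snr_percent = 0`` returns the pair unchanged (noise-free control).
    """
    if noise.snr_percent == 0:
        return pair
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale_x = math.sqrt(pair.x.var() * 100.0 / noise.snr_percent)
    scale_y = math.sqrt(pair.y.var() * 100.0 / noise.snr_percent)
    nx = rng.normal(0.0, scale_x, len(pair))
    ny = rng.normal(0.0, scale_y, len(pair))
    return TimeSeriesPair(pair.x + nx, pair.y + ny, pair.fs)


def synthesize_powerlaw_pair(
    beta_x: float,
    beta_y: float,
    n_samples: int = 8192,
    fs: float = 500.0,
    seed: int | np.random.Generator = 0,
) -> TimeSeriesPair:
    """Exact power-law pair with shared phases (inverse-FFT synthesis).

    Channel amplitudes are ``f**(-beta/2)`` on the one-sided grid with one
    shared uniform-random phase sequence, so the cross-spectral magnitude is
    exactly ``f**(-(beta_x+beta_y)/2)`` and the pair's theoretical
    cross-spectral exponent is ``(beta_x + beta_y) / 2`` with unit coherence
    at every bin.
    """
    for name, b in (("beta_x", beta_x), ("beta_y", beta_y)):
        if not (math.isfinite(b) and 0 <= b <= 2):
            raise ValidationError(f"{name} must lie in [0, 2], got {b}")
    if n_samples < 256:
        raise ValidationError(f"n_samples must be at least 256, got {n_samples}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    phases = rng.uniform(0, 2 * np.pi, len(freqs))
    phases[0] = 0.0
    if n_samples % 2 == 0:
        phases[-1] = 0.0  # Nyquist bin must be real

    def channel(beta: float) -> np.ndarray:
        amp = np.zeros(len(freqs))
        amp[1:] = freqs[1:] ** (-beta / 2)
        return np.fft.irfft(amp * np.exp(1j * phases), n_samples)

    return TimeSeriesPair(channel(beta_x), channel(beta_y), fs)
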