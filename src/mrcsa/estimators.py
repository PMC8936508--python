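"""Cross-spectral exponent fitting and the fractal power fraction.

The cross-spectral exponent beta_xy is the slope of the log-log linear fit to
the separated fractal cross-power spectrum, reported sign-reversed so that a
steeper 1/f decay gives a larger positive value.  Because a uniform frequency
grid over-represents high frequencies after the log transform, the log-power
is first resampled onto an evenly spaced log-frequency grid before ordinary
least squares.

The fractal fraction (in percent) is the ratio of summed fractal to summed
mixed cross-spectral power over a band; for a pair with no oscillatory
component it is close to 100, and it drops as narrow-band peaks contribute
power that the separation removes.  It is an upper bound on the complement of
the oscillatory contribution and is deliberately not clipped at 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ComputationError, SpectrumEstimate, ValidationError

__all__ = [
    "SlopeFit",
    "FractalFraction",
    "fit_spectral_slope",
    "fractal_fraction",
    "slope_squared_difference",
]

logger = logging.getLogger(__name__)

MIN_FIT_BINS = 10
MAX_LOG_GRID = 1000


@dataclass(frozen=True)
class SlopeFit:
    beta: float
    intercept: float
    band: tuple[float, float]
    n_points: int
    r_squared: float


@dataclass(frozen=True)
class FractalFraction:
    percent: float
    band: tuple[float, float]


def fit_spectral_slope(
    spec: SpectrumEstimate,
    band: tuple[float, float],
    which: str = "fractal",
) -> SlopeFit:
    """OLS fit of log10 power against log10 frequency on a log-even grid.

    Power values that are not strictly positive cannot be log-transformed;
    such bins are dropped with a warning.  At least ``MIN_FIT_BINS`` usable
    bins are required.
    """
    if which not in ("fractal", "mixed"):
        raise ValidationError(f"which must be 'fractal' or 'mixed', got {which!r}")
    power = spec.fractal if which == "fractal" else spec.mixed
    mask = spec.band_mask(band)
    if mask.sum() < MIN_FIT_BINS:
        raise ValidationError(
            f"band {band} contains only {int(mask.sum())} bins; at least {MIN_FIT_BINS} required"
        )
    freqs = spec.freqs[mask]
    pw = power[mask]
    positive = pw > 0
    if not positive.all():
        logger.warning(
            "dropping %d non-positive power bins from the slope fit", int((~positive).sum())
        )
        freqs, pw = freqs[positive], pw[positive]
    if len(pw) < MIN_FIT_BINS:
        raise ValidationError(
            f"only {len(pw)} usable bins remain in band {band}; at least {MIN_FIT_BINS} required"
        )

    log_f = np.log10(freqs)
    log_p = np.log10(pw)
    n_grid = min(len(log_f), MAX_LOG_GRID)
    grid = np.linspace(log_f[0], log_f[-1], n_grid)
    grid_p = np.interp(grid, log_f, log_p)

    design = np.column_stack([grid, np.ones_like(grid)])
    (slope, intercept), *_ = np.linalg.lstsq(design, grid_p, rcond=None)
    resid = grid_p - design @ np.array([slope, intercept])
    ss_tot = float(np.sum((grid_p - grid_p.mean()) ** 2))
    r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return SlopeFit(
        beta=float(-slope),
        intercept=float(intercept),
        band=band,
        n_points=n_grid,
        r_squared=r_squared,
    )


def fractal_fraction(spec: SpectrumEstimate, band: tuple[float, float]) -> FractalFraction:
    """Percentage of fractal to mixed cross-spectral power over ``band``."""
    mask = spec.band_mask(band)
    denom = float(spec.mixed[mask].sum())
    if denom <= 0:
        raise ComputationError(f"mixed cross-spectral power sums to {denom} over band {band}")
    return FractalFraction(
        percent=100.0 * float(spec.fractal[mask].sum()) / denom,
        band=band,
    )


def slope_squared_difference(beta_a: float, beta_b: float) -> float:
    """Squared difference between two cross-spectral exponents."""
    if not (np.isfinite(beta_a) and np.isfinite(beta_b)):
        raise ValidationError("exponents must be finite")
    return float((beta_a - beta_b) ** 2)
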