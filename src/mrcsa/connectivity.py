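"""Pairwise fractal connectivity over multichannel recordings.

For every unordered channel pair the fractal cross-spectrum is separated per
trial, the cross-spectral exponent and fractal fraction are fitted per trial,
and the resulting channels x channels matrices are averaged across trials.
The diagonal holds univariate (auto-spectral) exponents obtained by running
the same separation on (x, x).  The per-channel sum of off-diagonal exponents
is the node degree of the fractal connectivity graph.

Two conditions are compared edge-wise on paired subject averages: a
Lilliefors test gates the choice between a paired t-test (normal differences)
and a paired Wilcoxon signed-rank test, and p-values are corrected for
multiplicity over the edge family (the diagonal of auto exponents forms its
own, channel-sized family).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .core import MrcsaConfig, TimeSeriesPair, ValidationError, mrcsa
from .estimators import fit_spectral_slope, fractal_fraction

__all__ = [
    "MultichannelTrials",
    "ConnectivityResult",
    "ComparisonResult",
    "pairwise_mrcsa",
    "node_degree",
    "compare_conditions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MultichannelTrials:
    """Array of shape (channels, samples, trials) with a shared sampling rate."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim == 2:
            data = data[:, :, None]
        if data.ndim != 3:
            raise ValidationError(
                f"data must have shape (channels, samples[, trials]), got {data.shape}"
            )
        if data.shape[0] < 2:
            raise ValidationError("at least two channels are required")
        if not np.all(np.isfinite(data)):
            raise ValidationError("data contains non-finite values")
        if len(self.channel_labels) != data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel labels must be unique")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "data", data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class ConnectivityResult:
    """Trial-averaged exponent and fractal-fraction matrices."""

    beta_matrix: np.ndarray
    fraction_matrix: np.ndarray
    channel_labels: list[str]
    per_trial_beta: np.ndarray | None = None
    per_trial_fraction: np.ndarray | None = None


@dataclass(frozen=True)
class ComparisonResult:
    """Edge-wise paired statistics between two conditions."""

    edges: pd.DataFrame
    diagonal: pd.DataFrame
    correction: str
    alpha: float


def pairwise_mrcsa(trials: MultichannelTrials, config: MrcsaConfig | None = None) -> ConnectivityResult:
    """Fractal connectivity matrices from all unordered channel pairs.

    Exponents and fractions are fitted per trial and then averaged across
    trials (not fitted on averaged spectra).  A pair whose separation or fit
    fails is recorded as NaN with a warning.
    """
    if config is None:
        config = MrcsaConfig()
    config.validate_for(trials.fs)
    n_ch, _, n_tr = trials.data.shape
    beta = np.full((n_ch, n_ch, n_tr), np.nan)
    frac = np.full((n_ch, n_ch, n_tr), np.nan)
    for trial in range(n_tr):
        for i, j in itertools.combinations_with_replacement(range(n_ch), 2):
            pair = TimeSeriesPair(
                trials.data[i, :, trial], trials.data[j, :, trial], trials.fs
            )
            try:
                spec = mrcsa(pair, config)
                beta[i, j, trial] = fit_spectral_slope(spec, config.fit_band).beta
                frac[i, j, trial] = fractal_fraction(spec, config.fit_band).percent
            except Exception:
                logger.warning(
                    "separation failed for pair (%s, %s), trial %d; recording NaN",
                    trials.channel_labels[i],
                    trials.channel_labels[j],
                    trial,
                )
            beta[j, i, trial] = beta[i, j, trial]
            frac[j, i, trial] = frac[i, j, trial]
    return ConnectivityResult(
        beta_matrix=beta.mean(axis=2),
        fraction_matrix=frac.mean(axis=2),
        channel_labels=list(trials.channel_labels),
        per_trial_beta=beta,
        per_trial_fraction=frac,
    )


def node_degree(matrix: np.ndarray, include_diagonal: bool = False) -> np.ndarray:
    """Per-channel sum of edge exponents (diagonal excluded by default)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError(f"matrix must be square, got shape {matrix.shape}")
    total = matrix.sum(axis=1)
    return total if include_diagonal else total - np.diag(matrix)


def _paired_tests(diffs: np.ndarray, alpha: float) -> tuple[float, float, str]:
    """Lilliefors-gated paired test on an array of per-subject differences."""
    if np.allclose(diffs, diffs[0]):
        # degenerate: identical differences; Lilliefors undefined
        if np.allclose(diffs, 0.0):
            return 0.0, 1.0, "t"
        normal = True
    else:
        _, lf_p = lilliefors(diffs, dist="norm")
        normal = lf_p >= alpha
    if normal:
        stat, p = stats.ttest_1samp(diffs, 0.0)
        return float(stat), float(p), "t"
    stat, p = stats.wilcoxon(diffs, zero_method="wilcox", method="auto")
    return float(stat), float(p), "wilcoxon"


def _correct(pvals: np.ndarray, correction: str, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    method = {"bonferroni": "bonferroni", "fdr": "fdr_bh"}.get(correction)
    if method is None:
        raise ValidationError(f"correction must be 'bonferroni' or 'fdr', got {correction!r}")
    _, p_adj, *_ = multipletests(pvals, alpha=alpha, method=method)
    return p_adj, p_adj < alpha


def compare_conditions(
    a: list[ConnectivityResult],
    b: list[ConnectivityResult],
    correction: str = "bonferroni",
    alpha: float = 0.05,
    metric: str = "beta",
) -> ComparisonResult:
    """Paired edge-wise comparison of two conditions across subjects.

    ``a`` and ``b`` are per-subject results from matched recordings.  The
    off-diagonal edges are corrected as one family of n*(n-1)/2 tests; the
    diagonal (auto exponents) as its own family of n tests.
    """
    if len(a) != len(b):
        raise ValidationError(f"unmatched subjects: {len(a)} vs {len(b)}")
    if len(a) < 6:
        raise ValidationError(f"at least 6 paired subjects are required, got {len(a)}")
    labels = a[0].channel_labels
    for res in itertools.chain(a, b):
        if res.channel_labels != labels:
            raise ValidationError("all results must share the same channel labels")
    attr = {"beta": "beta_matrix", "fraction": "fraction_matrix"}.get(metric)
    if attr is None:
        raise ValidationError(f"metric must be 'beta' or 'fraction', got {metric!r}")
    mats_a = np.stack([getattr(r, attr) for r in a])  # subjects x ch x ch
    mats_b = np.stack([getattr(r, attr) for r in b])
    n_ch = mats_a.shape[1]

    records = []
    for i, j in itertools.combinations(range(n_ch), 2):
        diffs = mats_b[:, i, j] - mats_a[:, i, j]
        stat, p, test = _paired_tests(diffs, alpha)
        records.append(
            {"edge": f"{labels[i]}-{labels[j]}", "statistic": stat, "raw_p": p, "test_used": test}
        )
    edges = pd.DataFrame(records)
    edges["adjusted_p"], edges["significant"] = _correct(
        edges["raw_p"].to_numpy(), correction, alpha
    )

    diag_records = []
    for i in range(n_ch):
        diffs = mats_b[:, i, i] - mats_a[:, i, i]
        stat, p, test = _paired_tests(diffs, alpha)
        diag_records.append(
            {"edge": labels[i], "statistic": stat, "raw_p": p, "test_used": test}
        )
    diagonal = pd.DataFrame(diag_records)
    diagonal["adjusted_p"], diagonal["significant"] = _correct(
        diagonal["raw_p"].to_numpy(), correction, alpha
    )
    return ComparisonResult(edges=edges, diagonal=diagonal, correction=correction, alpha=alpha)
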