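import numpy as np
import pytest

from mrcsa import (
    McArfimaParams,
    MrcsaConfig,
    SegmentationScheme,
    TimeSeriesPair,
    simulate_mc_arfima,
    synthesize_powerlaw_pair,
)


@pytest.fixture(scope="session")
def fast_config() -> MrcsaConfig:
    """Reduced segmentation for quick pipeline tests; the h-grid stays full."""
    return MrcsaConfig(
        segmentation=SegmentationScheme(n_segments=5, fraction=0.9),
        fit_band=(0.5, 100.0),
    )


@pytest.fixture(scope="session")
def arfima_pair() -> TimeSeriesPair:
    """One default mixed-correlated ARFIMA pair (beta_uv = 0.5) at full scale."""
    return simulate_mc_arfima(McArfimaParams(), 10_000, 500.0, seed=42)


@pytest.fixture(scope="session")
def powerlaw_pair() -> TimeSeriesPair:
    """Shared-phase power-law oracle pair with exact cross exponent 0.5."""
    return synthesize_powerlaw_pair(0.4, 0.6, 8192, 500.0, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
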