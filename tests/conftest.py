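import numpy as np
import pytest

from kinetrans import FundamentalConstants, SpeciesState


@pytest.fixture
def balanced_params() -> FundamentalConstants:
    """All three steps on comparable timescales (no separation built in)."""
    return FundamentalConstants(
        "2D", d_plus=1.0, d_minus=1.2, e_plus=0.5, e_minus=0.9, k_plus=0.8, k_minus=0.6
    )


@pytest.fixture
def tf_regime_params() -> FundamentalConstants:
    """Thermal-fluctuation / adhesion-frequency regime: pre-binding steps fast,
    binding slow (k+ << e-), E^2D = 0.04."""
    return FundamentalConstants(
        "2D", d_plus=1.0e4, d_minus=1.0e4, e_plus=400.0, e_minus=1.0e4,
        k_plus=0.1, k_minus=0.5,
    )


@pytest.fixture
def all_free_state() -> SpeciesState:
    return SpeciesState(R=1e-3, L=1e-3, RL_star=0.0, RL=0.0, C=0.0)


def random_constants(rng: np.random.Generator, dimension: str = "2D") -> FundamentalConstants:
    """Log-uniform random rate constants over two decades around 1."""
    vals = 10.0 ** rng.uniform(-1, 1, size=6)
    return FundamentalConstants(dimension, *vals)
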