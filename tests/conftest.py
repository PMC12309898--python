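"""Shared fixtures: the (expensive) Monte Carlo forward model and sweeps."""

from __future__ import annotations

import numpy as np
import pytest

from hqbold import experiments
from hqbold.forward_models import MonteCarloForward

MC_PROTONS = 6000
MC_SEED = 1_000_004
SWEEP_SEED = 1


@pytest.fixture(scope="session")
def mc_forward() -> MonteCarloForward:
    """Session-wide Monte Carlo forward model (built once; ~seconds)."""
    return MonteCarloForward(n_protons=MC_PROTONS, seed=MC_SEED)


@pytest.fixture(scope="session")
def mc_sweep(mc_forward) -> "pd.DataFrame":  # noqa: F821
    """The 1000-state diffusive systematic-error sweep, computed once."""
    design = experiments.SweepDesign(n_states=1000, seed=SWEEP_SEED)
    return experiments.run_systematic_sweep(design, forward="mc", mc=mc_forward)


@pytest.fixture(scope="session")
def fixture_tables():
    from hqbold.synthetic_data import fixture_tables as _ft

    return _ft()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
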