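"""Shared fixtures.

The perturbed-model simulations behind a fault scan depend only on the
model and the sampling grid — not on the noise realization — so a single
session-scoped :class:`SimulationCache` per demo model is shared by every
test that scans it.
"""

import numpy as np
import pytest

from kinfault import (SamplingSpec, SimulationCache, build_demo_oscillator,
                      build_demo_steady, simulate)


@pytest.fixture(scope="session")
def steady_model():
    return build_demo_steady()


@pytest.fixture(scope="session")
def osc_model():
    return build_demo_oscillator()


@pytest.fixture(scope="session")
def steady_spec(steady_model):
    return SamplingSpec(steady_model.default_horizon_h, 6)


@pytest.fixture(scope="session")
def osc_spec(osc_model):
    return SamplingSpec(osc_model.default_horizon_h, 6)


@pytest.fixture(scope="session")
def steady_cache(steady_model, steady_spec):
    return SimulationCache(steady_model, steady_spec)


@pytest.fixture(scope="session")
def osc_cache(osc_model, osc_spec):
    return SimulationCache(osc_model, osc_spec)


@pytest.fixture(scope="session")
def steady_traj(steady_model, steady_spec):
    """Nominal (unperturbed) noise-free steady-model trajectory."""
    return simulate(steady_model, steady_spec)


@pytest.fixture(scope="session")
def osc_traj(osc_model, osc_spec):
    """Nominal noise-free oscillator trajectory."""
    return simulate(osc_model, osc_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
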