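import numpy as np
import pytest

from edsflow import ThermoContext, benchmark_system
from edsflow.potentials import HarmonicPotential


@pytest.fixture(scope="session")
def thermo():
    return ThermoContext()


@pytest.fixture(scope="session")
def benchmark_states():
    return benchmark_system()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def overlap_pair():
    """Two 1D harmonic states with overlapping wells: both the plain MC
    propagator and the replica-exchange top level are ergodic on them, so
    sampled distributions can be compared against exact references."""
    a = HarmonicPotential(np.array([1200.0]), np.array([-0.08]), 0.0, "A")
    b = HarmonicPotential(np.array([2500.0]), np.array([0.09]), 2.0, "B")
    return [a, b]
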