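import numpy as np
import pytest

from permeon import PoreModel, SimSpec, SpeciesSpec, simulate_ions
from permeon.synthetic import gaussian_feature, sum_potential


@pytest.fixture(scope="session")
def double_well_potential():
    """Asymmetric double feature: a 2 kBT barrier and a 1 kBT well."""
    return sum_potential(gaussian_feature(-5.0, 2.0, 2.0), gaussian_feature(5.0, -1.0, 2.0))


@pytest.fixture(scope="session")
def equilibrium_tracks(double_well_potential):
    """Long zero-voltage Langevin run in the double-well landscape,
    shared by the Boltzmann-inversion tests."""
    model = PoreModel(
        potential=double_well_potential,
        species=[SpeciesSpec("mono", 1, 10.0, 16)],
        voltage_mV=0.0,
    )
    spec = SimSpec(dt_ns=0.002, n_steps=100_000, save_stride=2, seed=101)
    return simulate_ions(model, spec)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
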