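import numpy as np
import pytest

from oxshift import synthetic
from oxshift.synthetic import GrowthModel, ImpulseParams, NoiseModel


@pytest.fixture(scope="session")
def o2_design():
    """Single-arm aerobic design, 9 time points, 4 replicates."""
    return synthetic.make_design(n_replicates=4, conditions=("O2",))


@pytest.fixture(scope="session")
def two_arm_design():
    return synthetic.make_design(n_replicates=3)


@pytest.fixture(scope="session")
def noisefree():
    return NoiseModel(injection_cv=0.0, feature_cv=0.0)


@pytest.fixture(scope="session")
def growth_o2():
    return {"O2": GrowthModel(), "An": GrowthModel()}


@pytest.fixture(scope="session")
def flat_table(o2_design, growth_o2, noisefree):
    """Noise-free table of three flat features."""
    profiles = {f: {"O2": ImpulseParams()} for f in ("met_a", "met_b", "met_c")}
    return synthetic.simulate_metabolomics(
        o2_design, profiles, growth_o2, noisefree, seed=0
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)
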