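import numpy as np
import pytest

from mesodpd import (build_unit_map, composition_from_weight_percent,
                     default_force_field, random_initial_configuration)


@pytest.fixture(scope="session")
def ff():
    return default_force_field()


@pytest.fixture(scope="session")
def unit_map():
    """Room-temperature water mapping (2 H2O per bead, density 3)."""
    return build_unit_map(298.15, 997.0, 2, 3)


@pytest.fixture(scope="session")
def water_box(ff):
    """Pure water at L=5, for fast engine checks."""
    comp = composition_from_weight_percent(5.0, 0.0, {}, ff)
    return random_initial_configuration(comp, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
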