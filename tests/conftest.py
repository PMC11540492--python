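import numpy as np
import pytest

from ecathsim import (
    ChemistryParams,
    ReactionNetwork,
    build_grid,
    default_segments,
    initial_composition,
)


@pytest.fixture(scope="session")
def network():
    return ReactionNetwork(ChemistryParams())


@pytest.fixture(scope="session")
def saline():
    """Default initial electrolyte: pH 5.5, 154.04 mol/m^3 NaCl."""
    return initial_composition(5.5, 154.04)


@pytest.fixture(scope="session")
def coarse_grid():
    """Default segment stack at reduced resolution for fast transport tests."""
    return build_grid(
        default_segments(),
        {"hub": 10, "luer_top": 3, "luer_bottom": 4, "tube": 40},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(17)
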