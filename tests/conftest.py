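import pytest

from pelletgrowth import (
    DimensionalScales,
    ModelParameters,
    RadialGrid,
    SolverConfig,
    initial_state,
)


@pytest.fixture(scope="session")
def fitted_params() -> ModelParameters:
    """The parameter point selected by the day-21/28 data fit."""
    return ModelParameters(kappa=0.3, sigma0=6.0)


@pytest.fixture(scope="session")
def scales() -> DimensionalScales:
    return DimensionalScales()


@pytest.fixture(scope="session")
def grid200() -> RadialGrid:
    return RadialGrid(200)


@pytest.fixture(scope="session")
def grid400() -> RadialGrid:
    return RadialGrid(400)


@pytest.fixture()
def small_pellet_state(grid200):
    """A fresh sigma0=2 pellet with its quasi-steady nutrient profile."""
    params = ModelParameters(kappa=0.3, sigma0=2.0)
    return params, initial_state(params, grid200, SolverConfig())
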