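import numpy as np
import pytest

from chase import CityMap, ModelParameters, PopulationState, generate_map, initial_state


@pytest.fixture
def small_map() -> CityMap:
    """Three cities with city 1 and city 2 equidistant from city 0."""
    return CityMap.from_coords([(0.0, 0.0), (1.0, 1.0), (1.0, -1.0)], K=500.0)


@pytest.fixture
def ten_city_map() -> CityMap:
    return generate_map(L=10, K_value=5000.0, seed=42)


@pytest.fixture
def fast_params() -> ModelParameters:
    """Benchmark parameters at a short horizon for cheap tests."""
    return ModelParameters(T=50)


def random_state(rng: np.random.Generator, L: int, scale: float = 1000.0) -> PopulationState:
    """A random non-negative population state with a sprinkling of zeros."""
    n = rng.random((L, L)) * scale
    n[rng.random((L, L)) < 0.2] = 0.0
    return PopulationState(n=n, t=0)
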