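"""Shared fixtures and hypothesis configuration for the test suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from morphodiet import gpa_align, make_template_outline
from morphodiet.synthetic_data import (
    ShapeGroupSpec,
    ShapeSimSpec,
    simulate_shape_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    return make_template_outline(n_fixed=2, n_semi=24)


@pytest.fixture(scope="session")
def small_template():
    return make_template_outline(n_fixed=2, n_semi=8)


@pytest.fixture(scope="session")
def two_group_shapes():
    """A small aligned two-group sample with a planted size contrast."""
    spec = ShapeSimSpec(
        n_fixed=2,
        n_semi=8,
        groups=[
            ShapeGroupSpec("A", 15, size_mean=60.0, size_sd=0.05),
            ShapeGroupSpec("B", 15, size_mean=78.0, size_sd=0.05),
        ],
        allometric_slope=0.0,
        landmark_noise_sd=0.01,
        seed=11,
    )
    configs, truth = simulate_shape_dataset(spec)
    shapes = gpa_align(configs)
    return shapes, truth


def random_config(rng: np.random.Generator, n: int = 10) -> np.ndarray:
    """A random well-spread 2-D point matrix."""
    return rng.uniform(-1.0, 1.0, size=(n, 2)) + np.column_stack(
        [np.arange(n) * 0.01, np.zeros(n)]
    )
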