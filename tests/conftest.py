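"""Shared fixtures: canonical parameter vectors and the seeded study population."""

import numpy as np
import pytest
from hypothesis import settings

from tibmorph.mesh_resection import PlanarContour
from tibmorph.synthetic import (
    ParameterVector,
    default_population_spec,
    make_contour,
    sample_population,
)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

#: one fixed seed for every stochastic fixture in the suite
SUITE_SEED = 42


@pytest.fixture(scope="session")
def male_params() -> ParameterVector:
    """Male gender-mean parameter vector (mm)."""
    return ParameterVector(ml=77.52, ap=49.26, map=51.79, lap=46.73,
                           cm=15.71, cl=16.35, mar=26.00, lar=23.00)


@pytest.fixture(scope="session")
def female_params() -> ParameterVector:
    """Female gender-mean parameter vector (mm)."""
    return ParameterVector(ml=67.51, ap=43.45, map=46.65, lap=40.45,
                           cm=12.87, cl=14.20, mar=22.86, lar=20.03)


@pytest.fixture(scope="session")
def pooled_params() -> ParameterVector:
    """Both-gender pooled mean parameter vector (mm)."""
    return ParameterVector(ml=72.52, ap=46.36, map=49.22, lap=43.59,
                           cm=14.29, cl=15.28, mar=24.43, lar=21.52)


@pytest.fixture(scope="session")
def male_contour(male_params):
    return make_contour(male_params)


@pytest.fixture(scope="session")
def population():
    """Measured synthetic study population: 240 subjects/gender, two sides."""
    return sample_population(
        default_population_spec(n_per_gender=240, seed=SUITE_SEED)
    )


@pytest.fixture(scope="session")
def population_right(population):
    """One independent record per subject (right side): 480 knees."""
    return population[population["side"] == "right"].reset_index(drop=True)


@pytest.fixture()
def square_contour() -> PlanarContour:
    """10 x 10 mm square centred at the origin."""
    return PlanarContour(
        points=np.array([[-5.0, -5.0], [5.0, -5.0], [5.0, 5.0], [-5.0, 5.0]])
    )


def ellipse_contour(a: float, b: float, n: int = 400) -> PlanarContour:
    """Polygonal ellipse with vertices exactly at the axis extremes."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return PlanarContour(
        points=np.column_stack([a * np.cos(th), b * np.sin(th)])
    )
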