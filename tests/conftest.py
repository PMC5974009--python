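import numpy as np
import pytest

from cinevol import PhantomSpec, analyze_study, generate_phantom


def circle_polygon(r: float, n: int = 400, centre=(0.0, 0.0)) -> np.ndarray:
    a = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([centre[0] + r * np.cos(a), centre[1] + r * np.sin(a)])


def ellipse_polygon(a: float, b: float, n: int = 2000) -> np.ndarray:
    t = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


def star_polygon(rng: np.random.Generator, n_min: int = 5, n_max: int = 40) -> np.ndarray:
    """Random simple polygon star-shaped about the origin.

    Angular gaps are drawn in [0.5, 1] before normalization, so the largest
    gap is at most 4*pi/n < pi for n >= 5 and the origin is strictly interior.
    """
    n = int(rng.integers(n_min, n_max + 1))
    u = rng.uniform(0.5, 1.0, n)
    angles = 2.0 * np.pi * np.cumsum(u) / u.sum() + rng.uniform(0.0, 2.0 * np.pi)
    radii = rng.uniform(0.5, 2.0, n)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def analyzed_default(default_phantom):
    study, truth = default_phantom
    curve, indices = analyze_study(study)
    return curve, indices, truth
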