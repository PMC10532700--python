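"""Shared fixtures: session-cached phantom cohorts and geometry helpers."""

import numpy as np
import pytest
from scipy import ndimage

from postop3d import PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def phantom_one():
    """One default-conditions phantom (seed 3)."""
    return make_phantom(PhantomConfig(seed=3))


@pytest.fixture(scope="session")
def phantom_noise_free():
    """One noise-free phantom (seed 3)."""
    return make_phantom(PhantomConfig(seed=3, noise_sd=0.0))


@pytest.fixture(scope="session")
def phantoms_noise_free_10():
    """Ten seeded noise-free phantoms (seeds 0..9)."""
    return [make_phantom(PhantomConfig(seed=s, noise_sd=0.0)) for s in range(10)]


@pytest.fixture(scope="session")
def phantoms_noisy_10():
    """Ten seeded phantoms at the default 20 HU noise (seeds 0..9)."""
    return [make_phantom(PhantomConfig(seed=s)) for s in range(10)]


def mask_surface_indices(mask_values: np.ndarray) -> np.ndarray:
    fg = mask_values > 0
    return np.argwhere(fg & ~ndimage.binary_erosion(fg)).astype(float)


def mean_point_error(t_a, t_b, points: np.ndarray) -> float:
    """Mean Euclidean distance between two transforms' images of points."""
    return float(np.linalg.norm(t_a.apply(points) - t_b.apply(points), axis=1).mean())


def sign_agnostic_angle_deg(a, b) -> float:
    d = abs(float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))))
    return float(np.degrees(np.arccos(min(d, 1.0))))
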