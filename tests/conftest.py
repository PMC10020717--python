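"""Shared fixtures: small synthetic cases, profiles and image corpora.

Everything is generated programmatically at test time; session scope keeps
the geometry/physics fixtures to one construction each.
"""

from __future__ import annotations

import numpy as np
import pytest

from hemoline.geometry import GeometryParams, build_case, build_straight_tube
from hemoline.oracle import OracleParams, sample_fields, solve_profile


@pytest.fixture(scope="session")
def default_case():
    return build_case(GeometryParams(ava=0.8, seed=1), label="fixture-case")


@pytest.fixture(scope="session")
def default_profile(default_case):
    return solve_profile(default_case, 400.0)


@pytest.fixture(scope="session")
def default_samples(default_case, default_profile):
    return sample_fields(default_case, default_profile, seed=7, n_samples=64)


@pytest.fixture(scope="session")
def straight_tube():
    return build_straight_tube(radius_mm=12.0, length_mm=240.0)


def make_circle_images(
    n: int, seed: int, grid: int = 68, window_mm: float = 50.0,
    r_range: tuple[float, float] = (4.0, 16.0),
) -> tuple[list[np.ndarray], np.ndarray]:
    """Centered circle rasters over the standard window; returns images and radii."""
    rng = np.random.default_rng(seed)
    radii = rng.uniform(*r_range, size=n)
    half = window_mm / 2.0
    px = window_mm / grid
    centers = -half + (np.arange(grid) + 0.5) * px
    xx, yy = np.meshgrid(centers, centers)
    images = [(xx**2 + yy**2 <= r**2) for r in radii]
    return images, radii


@pytest.fixture(scope="session")
def circle_corpus():
    train, train_r = make_circle_images(300, seed=5)
    held, held_r = make_circle_images(60, seed=6)
    return {"train": train, "train_r": train_r, "held": held, "held_r": held_r}
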