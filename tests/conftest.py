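import numpy as np
import pytest

from cellcryst.synthgen import GeneratorConfig


def point_in_polygon(px: float, py: float, poly: np.ndarray) -> bool:
    """Independent even-odd (crossing number) point-in-polygon test.

    Classic ray-casting loop, deliberately written without reference to the
    package's scanline rasterizer so the two can disagree.
    """
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def brute_force_rasterize(poly: np.ndarray, shape) -> np.ndarray:
    """Oracle rasterization: test every pixel center independently."""
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            mask[r, c] = point_in_polygon(c + 0.5, r + 0.5, poly)
    return mask


def random_simple_polygon(rng: np.random.Generator, size: float,
                          n_min: int = 3, n_max: int = 9) -> np.ndarray:
    """Random star-shaped polygon (simple by construction)."""
    n = int(rng.integers(n_min, n_max + 1))
    angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    radii = rng.uniform(0.15 * size, 0.48 * size, n)
    cx, cy = rng.uniform(0.3 * size, 0.7 * size, 2)
    return np.stack([cx + radii * np.cos(angles),
                     cy + radii * np.sin(angles)], axis=1)


@pytest.fixture(scope="session")
def desk_config_G():
    return GeneratorConfig.for_target("G", scale="desk")


@pytest.fixture(scope="session")
def desk_config_H():
    return GeneratorConfig.for_target("H", scale="desk")


@pytest.fixture(scope="session")
def easy_config():
    return GeneratorConfig.easy(128)
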