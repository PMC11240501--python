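"""Shared fixtures: rasterized reference shapes and small synthetic images."""

import numpy as np
import pytest
from skimage import draw

from astromorph.morphometry import extract_instances


def instance_from_mask(mask: np.ndarray, intensity=None, mpp: float = 1.0):
    """Single NucleusInstance from a boolean mask (label 1)."""
    instances = extract_instances(mask.astype(np.uint16), intensity, mpp=mpp)
    assert len(instances) == 1
    return instances[0]


def disk_mask(radius: int, pad: int = 4) -> np.ndarray:
    """Filled disk by the pixel-center rule (d <= r), the Gauss circle count."""
    side = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:side, :side]
    c = side // 2
    return ((yy - c) ** 2 + (xx - c) ** 2 <= radius**2).astype(np.uint16)


def ellipse_mask(a: int, b: int, rotation: float = 0.0, pad: int = 4) -> np.ndarray:
    """Axis-aligned (or rotated) filled ellipse with semi-axes a (rows), b (cols)."""
    side = 2 * (max(a, b) + pad) + 1
    mask = np.zeros((side, side), dtype=np.uint16)
    rr, cc = draw.ellipse(side // 2, side // 2, a, b, shape=mask.shape, rotation=rotation)
    mask[rr, cc] = 1
    return mask


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240703)
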