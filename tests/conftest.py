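"""Shared fixtures: digital phantoms built programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from tsradiomics import ImageVolume, LesionRecord, LesionType, ROIMask

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_sphere_mask(radius: int, pad: int = 2, spacing=(1.0, 1.0, 1.0)) -> ROIMask:
    """Solid digital sphere: voxel centers within ``radius`` of the middle."""
    half = radius + pad
    n = 2 * half + 1
    ax = np.arange(n) - half
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    fg = X**2 + Y**2 + Z**2 <= radius**2
    return ROIMask(fg, spacing)


def make_lesion(radius=8, core=60.0, rim=20.0, noise_sd=10.0, seed=7) -> LesionRecord:
    """Core/rim sphere phantom with mild noise, as a complete LesionRecord."""
    mask = make_sphere_mask(radius)
    rng = np.random.default_rng(seed)
    half = (mask.voxels.shape[0] - 1) // 2
    ax = np.arange(mask.voxels.shape[0]) - half
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2) / radius
    rho_c = (2 / 3) ** (1 / 3)
    vox = np.full(mask.voxels.shape, -1000.0)
    ramp = np.clip((r - rho_c) / (1 - rho_c), 0, 1)
    vox[mask.voxels] = core + (rim - core) * ramp[mask.voxels]
    if noise_sd > 0:
        vox = vox + rng.normal(0, noise_sd, vox.shape)
    image = ImageVolume(vox, mask.spacing)
    return LesionRecord("P0", "P0_L0", LesionType.PRIMARY, 2.0 * radius, image, mask)


def random_phantom(shape=(8, 8, 8), seed=0, p_fg=0.6):
    """Random small image + random (non-empty) mask for oracle comparisons."""
    rng = np.random.default_rng(seed)
    vox = rng.normal(0, 50, shape)
    fg = rng.random(shape) < p_fg
    if not fg.any():
        fg[tuple(s // 2 for s in shape)] = True
    return ImageVolume(vox, (1.0, 1.0, 1.0)), ROIMask(fg, (1.0, 1.0, 1.0))


@pytest.fixture
def sphere_mask():
    return make_sphere_mask(10)


@pytest.fixture
def lesion():
    return make_lesion()
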