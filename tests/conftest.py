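"""Shared fixtures: small synthetic scenes and analysis helpers.

Fixture scales are deliberately small (8-12 slices of 128-160 px planes,
15-150 cells) so the whole suite runs on one CPU in minutes while keeping
pixel-ratio statistics stable.
"""

from __future__ import annotations

import numpy as np
import pytest

from cellfate3d.image_io import ChannelRole
from cellfate3d.preprocess import CorrectionParams, correct_illumination
from cellfate3d.threshold import estimate_stack_threshold, segment_foreground
from cellfate3d.synthetic import SceneParams, simulate_scene, render_channel

#: blur scale used throughout the tests (planes are 128-224 px)
TEST_SIGMA = 25.0


@pytest.fixture
def correction() -> CorrectionParams:
    return CorrectionParams(sigma_px=TEST_SIGMA)


def corrected_planes(stack_planes, sigma_px: float = TEST_SIGMA) -> np.ndarray:
    params = CorrectionParams(sigma_px=sigma_px)
    return np.stack([correct_illumination(p, params) for p in stack_planes])


def analyze_channel(scene, role: ChannelRole, central_fraction: float = 0.2):
    """Render, correct, threshold, and segment one channel of a scene."""
    stack = render_channel(scene, role)
    planes = corrected_planes(stack.planes)
    decision = estimate_stack_threshold(planes, central_fraction=central_fraction)
    masks = np.stack([segment_foreground(p, decision) for p in planes])
    return planes, decision, masks


@pytest.fixture
def nuclei_scene():
    """A default-physics scene dense enough for stable statistics."""
    return simulate_scene(SceneParams(n_cells=100, volume_shape=(12, 128, 128), seed=11))


@pytest.fixture
def blank_scene():
    """A well with no cells: background, vignetting bias, and noise only."""
    return simulate_scene(SceneParams(n_cells=0, volume_shape=(12, 128, 128), seed=5))


def halo_scene(seed: int):
    """Cells packed at the z-center of a shallow stack: the extreme slices
    contain only out-of-focus halos (the failure mode the central-slice
    thresholding rule exists to prevent)."""
    return simulate_scene(
        SceneParams(n_cells=15, volume_shape=(8, 160, 160), seed=seed, z_range=(3.0, 4.0))
    )


HALO_EDGE_SLICES = [0, 1, 6, 7]
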