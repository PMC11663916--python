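"""Shared fixtures: small grids, masks, and a miniature effect cohort."""

import numpy as np
import pytest

from restpipe.core_io import BrainMask, VolumeGrid
from restpipe.synthetic import CohortSpec, EffectSpec, generate_cohort


def make_grid(shape=(12, 12, 12), voxel_mm=3.0, origin=None):
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_mm
    if origin is None:
        origin = -(np.asarray(shape) - 1) / 2.0 * voxel_mm
    affine[:3, 3] = origin
    return VolumeGrid(tuple(shape), affine)


@pytest.fixture
def grid():
    return make_grid()


@pytest.fixture
def full_mask(grid):
    return BrainMask(np.ones(grid.shape, dtype=bool), grid)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def tiny_effect_spec(seed=7, **overrides):
    """A fast-to-generate cohort with one amplitude+synchrony effect."""
    params = dict(
        n_per_group=6,
        shape=(16, 16, 16),
        n_volumes=80,
        effects=(
            EffectSpec("amplitude", (6, 6, 6), 6.0, 0.5),
            EffectSpec("synchrony", (6, 6, 6), 6.0, 0.5),
        ),
        cognition_coupling={"WM": 30.0, "SustA": 30.0},
        seed=seed,
    )
    params.update(overrides)
    return CohortSpec(**params)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(tiny_effect_spec())
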