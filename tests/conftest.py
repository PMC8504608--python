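import numpy as np
import pytest

from icksim import DoseGrid, GridSpec, StructureMask, TargetSpec, build_phantom


@pytest.fixture(scope="session")
def sphere_phantom():
    """Single calibrated 8 mm GTV sphere on the study-resolution 1.25 mm grid."""
    target = TargetSpec(center=(0.0, 0.0, 0.0), gtv_radius=8.0)
    return build_phantom([target], brain_radius_mm=30.0)


@pytest.fixture(scope="session")
def coarse_two_target_phantom():
    """Two lesions, one proximal (25 mm) and one distal (80 mm), coarse grid."""
    targets = [
        TargetSpec(center=(25.0, 0.0, 0.0), gtv_radius=6.0),
        TargetSpec(center=(-80.0, 0.0, 0.0), gtv_radius=6.0),
    ]
    return build_phantom(targets, spacing_mm=2.5, brain_radius_mm=100.0)


def random_dose_and_mask(rng, shape=(8, 8, 8), spacing=2.0, dose_max=25.0):
    """Small random dose grid plus a random non-empty mask on the same lattice."""
    grid = GridSpec(shape=shape, spacing=(spacing,) * 3)
    dose = DoseGrid(rng.uniform(0.0, dose_max, size=shape), grid)
    vox = rng.random(shape) < 0.4
    if not vox.any():
        vox[tuple(rng.integers(0, s) for s in shape)] = True
    return dose, StructureMask("m", vox, grid)
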