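"""Shared fixtures: small, cached phantoms and geometries for fast tests."""

import numpy as np
import pytest

from fdmar.phantoms import (MATERIALS, ScenarioConfig, Phantom, generate_phantom,
                            LABEL_SOFT)
from fdmar.projector import PhysicsModel, default_geometry


@pytest.fixture(scope="session")
def coil_phantom_128():
    return generate_phantom(ScenarioConfig(implant_kind="coil", grid_size=128,
                                           residual_filling_present=True, noise_seed=7))


@pytest.fixture(scope="session")
def nometal_phantom_128():
    return generate_phantom(ScenarioConfig(implant_kind="none", grid_size=128,
                                           noise_seed=7))


@pytest.fixture(scope="session")
def geometry_128(coil_phantom_128):
    return default_geometry("5s", 128, coil_phantom_128.voxel_size_mm)


@pytest.fixture(scope="session")
def flat_materials():
    """Energy-independent materials: polychromatic == monochromatic."""
    from fdmar.phantoms import MaterialSpec

    energies = (50.0, 60.0, 70.0, 80.0, 90.0)
    return {
        1: MaterialSpec("flat_soft", energies, (0.02,) * 5),
        2: MaterialSpec("flat_bone", energies, (0.05,) * 5),
        3: MaterialSpec("flat_contrast", energies, (0.04,) * 5),
        4: MaterialSpec("flat_metal", energies, (0.60,) * 5),
    }


@pytest.fixture()
def disk_phantom_96(flat_materials):
    """Uniform soft-tissue disk with flat (energy-independent) attenuation."""
    n = 96
    voxel = 153.6 / n
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    disk = (yy - c) ** 2 + (xx - c) ** 2 <= (0.35 * n) ** 2
    labels = np.where(disk, LABEL_SOFT, 0).astype(np.uint8)
    att = np.where(disk, 0.02, 0.0)
    return Phantom(
        attenuation_ref=att, labels=labels, voxel_size_mm=voxel,
        roi_table={"disk": disk}, truth={"residual_filling_present": False},
        materials=flat_materials,
    )
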