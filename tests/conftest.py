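import numpy as np
import pytest

from dvhpredict import DoseGrid, PhantomSpec, StructureMask, VolumeGrid


@pytest.fixture
def unit_grid5():
    """5^3 grid, 1 mm isotropic, voxel centers at integer mm."""
    return VolumeGrid(shape=(5, 5, 5), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))


@pytest.fixture
def small_spec():
    """Fast phantom: coarse 24^3 lattice, geometry scaled to fit."""
    return PhantomSpec(
        shape=(24, 24, 24),
        spacing=(8.0, 8.0, 8.0),
        target_radii_mm=(20.0, 20.0, 50.0),
        center_jitter_mm=4.0,
        seed=7,
    )


def make_mask(grid, occupancy, name="S", role="oar"):
    return StructureMask(grid=grid, name=name, role=role, occupancy=occupancy)


def make_target(grid, occupancy, name="PTV"):
    return StructureMask(grid=grid, name=name, role="target", occupancy=occupancy)


def make_dose(grid, values):
    return DoseGrid(grid=grid, dose=np.broadcast_to(np.asarray(values, float), grid.shape).copy())
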