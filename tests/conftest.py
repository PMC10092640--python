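import numpy as np
import pytest

from epilayer.core import NucleiTable, NucleusRecord

#: scaled-down field used throughout the tests: preset densities/heights/
#: sigmas unchanged, smaller field and coarser voxels to keep runs fast.
TEST_SCALE = dict(
    field_um=(150.0, 150.0), voxel_xy_um=1.0, voxel_z_um=0.25, noise_sd=0.05
)


def table_from_z(zs, volumes=None, field=(100.0, 100.0)):
    """Build a NucleiTable from z positions (xy placed trivially)."""
    zs = np.asarray(zs, dtype=float)
    if volumes is None:
        volumes = np.full(len(zs), 500.0)
    records = [
        NucleusRecord(
            id=str(i), x_um=1.0 + 0.01 * i, y_um=1.0, z_um=float(z), volume_um3=float(v)
        )
        for i, (z, v) in enumerate(zip(zs, volumes))
    ]
    return NucleiTable(records=records, field_width_um=field[0], field_height_um=field[1])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
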