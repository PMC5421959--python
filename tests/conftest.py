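import numpy as np
import pytest

import bolusforge as bf
from bolusforge.core import Volume3D


@pytest.fixture(scope="session")
def default_phantom():
    """The standard study phantom: 96x96x64 @ 1 mm, wall 15 +/- 5 mm."""
    spec = bf.PhantomSpec(seed=0)
    vol, structs = bf.generate_chest_phantom(spec)
    return spec, vol, structs


@pytest.fixture(scope="session")
def small_phantom():
    """A coarse phantom for fast I/O and geometry tests."""
    spec = bf.PhantomSpec(
        grid_shape=(32, 32, 24),
        chest_wall_base_mm=8.0,
        chest_wall_variation_mm=4.0,
        variation_wavelength_mm=25.0,
        skin_y_mm=8.0,
        skin_curvature_mm=1.0,
        lung_margin_mm=6.0,
        body_margin_mm=2.0,
        heart_center_mm=(12.0, 24.0, 12.0),
        heart_radius_mm=4.0,
        seed=11,
    )
    vol, structs = bf.generate_chest_phantom(spec)
    return spec, vol, structs


@pytest.fixture
def sphere_mask():
    """Digitised sphere of radius 20 mm at 1 mm spacing."""
    n = 48
    x = np.arange(n) - n / 2 + 0.5
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    mask = (X**2 + Y**2 + Z**2) <= 20.0**2
    return Volume3D(mask.astype(float), (1.0, 1.0, 1.0))


def column_depth_oracle(structs):
    """Independent chest-wall depth measurement: per-(x,z) column voxel
    counting on the masks, no geometry code shared with the pipeline."""
    body = structs[bf.BODY]
    lung = structs[bf.LUNG_IPSI]
    dy = structs.grid.spacing_mm[1]
    nx, ny, nz = body.shape
    out = np.full((nx, nz), np.nan)
    for ix in range(nx):
        for iz in range(nz):
            bcol = np.flatnonzero(body[ix, :, iz])
            lcol = np.flatnonzero(lung[ix, :, iz])
            if bcol.size and lcol.size and lcol[0] > bcol[0]:
                out[ix, iz] = (lcol[0] - bcol[0]) * dy
    return out
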