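import numpy as np
import pytest

from mbrtplan.beams import Field, ScenarioSet, build_dose_influence, nominal_only
from mbrtplan.geometry import Structure, VoxelGrid


def water_grid(n=24, spacing=4.0):
    """Homogeneous water cube centered on the origin."""
    shape = (n, n, n)
    extent = n * spacing
    origin = (-extent / 2 + spacing / 2,) * 3
    return VoxelGrid(shape, (spacing,) * 3, origin, np.ones(shape))


def sphere_structure(grid, center, radius, name="s", role="target"):
    xs, ys, zs = grid.voxel_centers()
    dx, dy, dz = xs - center[0], ys - center[1], zs - center[2]
    r2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    return Structure(name, r2 <= radius**2, role)


@pytest.fixture
def small_water_grid():
    return water_grid(n=24, spacing=4.0)


@pytest.fixture
def tiny_case():
    """Small homogeneous phantom with a central target and one lateral OAR."""
    grid = water_grid(n=20, spacing=5.0)
    target = sphere_structure(grid, (0, 0, 0), 14.0, "ctv", "target")
    oar = sphere_structure(grid, (25, 0, 0), 10.0, "oar", "oar")
    body = Structure("body", np.ones(grid.shape, bool), "body")
    return grid, [body, target, oar]


def tiny_influence(grid, structures, fields=None, scenarios=None, stride=1):
    if fields is None:
        fields = [
            Field("ph0", "photon", 6.0, 0.0, n_rows=6, n_cols=6),
            Field("el0", "electron", 12.0, 90.0, n_rows=6, n_cols=6, ssd_mm=723.0),
        ]
    if scenarios is None:
        scenarios = nominal_only()
    return build_dose_influence(fields, grid, structures, scenarios, normal_tissue_stride=stride)
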