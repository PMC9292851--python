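"""Voxel grids, structure masks, margin operations and the synthetic phantom.

Coordinate convention (shared by every module): voxel indices are 0-based,
world coordinates are voxel centers in mm, and the grid axes map to patient
axes x = left-right (LR), y = anterior-posterior (AP), z = superior-inferior
(SI).  Margin and crop operations are defined through the Euclidean distance
transform in mm so that "isotropic" keeps its geometric meaning under
anisotropic voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

#: density assigned to air voxels; strictly positive so that line integrals
#: through air never divide by zero downstream.
AIR_DENSITY = 0.001


@dataclass
class VoxelGrid:
    """Regular 3D scalar field (relative density, water = 1.0, or dose in Gy).

    Parameters
    ----------
    shape : (nx, ny, nz) voxel counts along LR / AP / SI.
    spacing_mm : voxel spacing along each axis, all > 0.
    origin_mm : world position of the center of voxel (0, 0, 0).
    values : array of shape ``shape``; non-negative.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        self.values = np.asarray(self.values, dtype=float)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.values.shape != self.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("grid values must be non-negative")

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1D world-coordinate axes (mm) of voxel centers along x, y, z."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def world_to_index(self, pos_mm: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm coordinates to fractional voxel indices."""
        pos_mm = np.asarray(pos_mm, dtype=float)
        return (pos_mm - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class Structure:
    """Named boolean mask on a :class:`VoxelGrid`."""

    name: str
    mask: np.ndarray
    role: str = "oar"  # one of target, oar, body, normal_tissue, prv, ptv

    _ROLES = ("target", "oar", "body", "normal_tissue", "prv", "ptv")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.role not in self._ROLES:
            raise ValueError(f"unknown structure role {self.role!r}")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def volume_mm3(self, grid: VoxelGrid) -> float:
        return self.voxel_count * grid.voxel_volume_mm3


@dataclass
class SyntheticCaseSpec:
    """Parameters of the synthetic head-like phantom.

    The phantom emulates a cranial/head-and-neck planning geometry: an
    ellipsoidal body contour, a spherical (or C-shaped) CTV a couple of
    centimeters under the anterior surface — shallow enough to be in reach
    of clinical electron energies — a handful of spherical OARs at varying
    distance from the CTV, and an optional bony shell under the skin.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    body_semi_axes_mm: tuple[float, float, float] = (80.0, 90.0, 92.0)
    ctv_shape: str = "sphere"  # "sphere" or "c_shape"
    ctv_center_mm: tuple[float, float, float] | None = None
    ctv_radius_mm: float = 15.0
    ctv_depth_mm: float | None = 20.0  # depth below anterior surface; overrides center
    oars: Sequence[dict] = field(
        default_factory=lambda: [
            {"name": "oar_abutting", "offset_mm": (0.0, 28.0, 0.0), "radius_mm": 10.0},
            {"name": "oar_near", "offset_mm": (32.0, 10.0, 12.0), "radius_mm": 9.0},
            {"name": "oar_distant", "offset_mm": (-30.0, 34.0, -20.0), "radius_mm": 11.0},
        ]
    )
    bone_shell: bool = True
    bone_density: float = 1.5
    bone_thickness_mm: float = 6.0
    seed: int = 0


def _ellipsoid_mask(grid: VoxelGrid, center: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    xs, ys, zs = grid.voxel_centers()
    dx = (xs - center[0]) / semi_axes[0]
    dy = (ys - center[1]) / semi_axes[1]
    dz = (zs - center[2]) / semi_axes[2]
    return (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    ) <= 1.0


def _sphere_mask(grid: VoxelGrid, center: np.ndarray, radius: float) -> np.ndarray:
    return _ellipsoid_mask(grid, np.asarray(center), np.array([radius] * 3))


def make_synthetic_case(spec: SyntheticCaseSpec) -> tuple[VoxelGrid, list[Structure]]:
    """Build the density grid and structure set of a synthetic case.

    Returns the density grid (body 1.0, bone shell ``bone_density``, outside
    air ``AIR_DENSITY``) and the structures: body, CTV (role target), the
    OARs and the normal-tissue shell (body minus CTV and OARs).
    Deterministic for a fixed spec (the seed is recorded for provenance and
    reserved for future randomized anatomy; the default anatomy is analytic).
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    extent = spacing * np.asarray(shape)
    origin = tuple(-extent / 2 + spacing / 2)
    grid = VoxelGrid(shape, tuple(spacing), origin, np.full(shape, AIR_DENSITY))

    body_center = np.zeros(3)
    semi = np.asarray(spec.body_semi_axes_mm, dtype=float)
    body_mask = _ellipsoid_mask(grid, body_center, semi)
    if not body_mask.any():
        raise ValueError("body ellipsoid does not intersect the grid")

    # CTV center: either explicit, or at the requested depth below the
    # anterior (-y) surface of the body along the AP axis.
    if spec.ctv_center_mm is not None:
        ctv_center = np.asarray(spec.ctv_center_mm, dtype=float)
    else:
        depth = float(spec.ctv_depth_mm if spec.ctv_depth_mm is not None else 20.0)
        ctv_center = np.array([0.0, -semi[1] + depth, 0.0])

    inside = np.sum(((ctv_center - body_center) / semi) ** 2) <= 1.0
    if not inside:
        raise ValueError("CTV center lies outside the body contour")

    if spec.ctv_shape == "sphere":
        ctv_mask = _sphere_mask(grid, ctv_center, spec.ctv_radius_mm)
    elif spec.ctv_shape == "c_shape":
        # C-shape: sphere minus a notch sphere displaced posteriorly.
        outer = _sphere_mask(grid, ctv_center, spec.ctv_radius_mm)
        notch_center = ctv_center + np.array([0.0, 0.6 * spec.ctv_radius_mm, 0.0])
        notch = _sphere_mask(grid, notch_center, 0.7 * spec.ctv_radius_mm)
        ctv_mask = outer & ~notch
    else:
        raise ValueError(f"unknown ctv_shape {spec.ctv_shape!r}")
    ctv_mask &= body_mask
    if not ctv_mask.any():
        raise ValueError("CTV mask is empty on this grid")

    density = np.full(shape, AIR_DENSITY)
    density[body_mask] = 1.0
    if spec.bone_shell:
        inner = _ellipsoid_mask(grid, body_center, semi - spec.bone_thickness_mm)
        density[body_mask & ~inner] = spec.bone_density
    grid.values = density

    structures = [Structure("body", body_mask, "body"), Structure("ctv", ctv_mask, "target")]
    oar_masks = []
    for oar in spec.oars:
        center = ctv_center + np.asarray(oar["offset_mm"], dtype=float)
        if np.sum(((center - body_center) / semi) ** 2) > 1.0:
            raise ValueError(f"OAR {oar['name']!r} center lies outside the body")
        mask = _sphere_mask(grid, center, float(oar["radius_mm"])) & body_mask & ~ctv_mask
        structures.append(Structure(oar["name"], mask, "oar"))
        oar_masks.append(mask)

    nt = make_normal_tissue(
        Structure("body", body_mask, "body"),
        [s for s in structures if s.role in ("target", "oar")],
    )
    structures.append(nt)
    return grid, structures


def _edt_mm(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Euclidean distance (mm) from each voxel to the nearest True voxel."""
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def expand_margin(s: Structure, grid: VoxelGrid, margin_mm: float) -> Structure:
    """Isotropic 3D dilation of a mask by ``margin_mm`` (EDT <= margin)."""
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    if margin_mm == 0:
        return Structure(s.name, s.mask.copy(), s.role)
    dist = _edt_mm(s.mask, grid.spacing_mm)
    return Structure(s.name, dist <= margin_mm, s.role)


def crop_from_body(s: Structure, body: Structure, grid: VoxelGrid, crop_mm: float) -> Structure:
    """Remove voxels of ``s`` closer than ``crop_mm`` to the body surface.

    The body surface is the boundary of the body mask; a voxel's distance to
    the surface is its Euclidean distance to the nearest non-body voxel.
    Voxels outside the body are always removed.
    """
    if not body.mask.any():
        raise ValueError("body mask is empty")
    if crop_mm < 0:
        raise ValueError("crop distance must be non-negative")
    depth = ndimage.distance_transform_edt(body.mask, sampling=grid.spacing_mm)
    keep = s.mask & body.mask & (depth >= crop_mm)
    if crop_mm == 0:
        keep = s.mask & body.mask
    return Structure(s.name, keep, s.role)


def make_normal_tissue(body: Structure, excluded: Sequence[Structure]) -> Structure:
    """Body minus the union of the excluded masks (targets and OARs)."""
    mask = body.mask.copy()
    for s in excluded:
        if s.mask.shape != mask.shape:
            raise ValueError("excluded mask shape differs from body mask")
        mask &= ~s.mask
    return Structure("normal_tissue", mask, "normal_tissue")
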