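"""Fields, beamlets, scenario sets and the analytic pencil-beam dose engines.

The photon and electron beamlet engines are analytic kernels, not transport
codes: they exist to give the optimizer the dosimetric contrasts it exploits
in practice — the sharp lateral penumbra and exponential depth falloff of
megavoltage photons versus the broad penumbra and finite practical range of
electron beams at shortened SSD.  Both engines share one geometry path; the
optimizer downstream never branches on modality.

Setup-error scenarios are systematic patient translations.  A patient shift
``s`` is modeled by translating the beam by ``-s`` relative to the voxel
grid under the isocenter-shift (static dose cloud) approximation: the
scenario dose is the nominal dose field translated by ``-s``,
``D_s(r) = D_0(r + s)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.special import erf

from .geometry import VoxelGrid, Structure

SAD_MM = 1000.0
BEAMLET_MM = 5.0  # beamlet edge length at the isocenter plane

ELECTRON_ENERGIES_MEV = (6.0, 9.0, 12.0, 15.0, 18.0, 22.0)
PHOTON_ENERGY_MV = 6.0

# photon depth-dose parameters (6 MV): buildup to d_max then exponential
PHOTON_DMAX_MM = 15.0
PHOTON_MU_PER_MM = 0.005
# lateral Gaussian widths (mm) as a function of water-equivalent depth (mm)
PHOTON_SIGMA0_MM, PHOTON_SIGMA_SLOPE = 3.0, 0.02
ELECTRON_SIGMA0_MM, ELECTRON_SIGMA_SLOPE = 4.0, 0.1
# bremsstrahlung tail for high electron energies
BREMS_FRACTION = 0.02
BREMS_MU_PER_MM = 0.005
BREMS_MIN_ENERGY_MEV = 15.0


@dataclass
class Field:
    """One beam: a direction and modality (and energy for electrons).

    Every direction/energy combination of an electron beam is its own field.
    The beamlet grid is ``n_rows x n_cols`` elements of 5 x 5 mm^2 at the
    isocenter plane; rows run along SI (the MLC leaf rows), columns along the
    in-plane transverse axis.  ``jaw_rect`` = (row0, row1, col0, col1),
    half-open, defaults to the full beamlet grid.
    """

    id: str
    modality: str
    energy: float
    gantry_angle_deg: float
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_rows: int = 10
    n_cols: int = 10
    ssd_mm: float | None = None
    jaw_rect: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("photon", "electron"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "electron":
            if float(self.energy) not in ELECTRON_ENERGIES_MEV:
                raise ValueError(
                    f"electron energy must be one of {ELECTRON_ENERGIES_MEV} MeV"
                )
        elif float(self.energy) != PHOTON_ENERGY_MV:
            raise ValueError("photon fields are 6 MV")
        if self.jaw_rect is None:
            self.jaw_rect = (0, self.n_rows, 0, self.n_cols)
        r0, r1, c0, c1 = self.jaw_rect
        if not (0 <= r0 < r1 <= self.n_rows and 0 <= c0 < c1 <= self.n_cols):
            raise ValueError("jaw_rect outside beamlet grid")

    @property
    def n_beamlets(self) -> int:
        r0, r1, c0, c1 = self.jaw_rect
        return (r1 - r0) * (c1 - c0)

    def beamlet_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Isocenter-plane center offsets (mm): (row centers v, col centers u)."""
        rows = (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * BEAMLET_MM
        cols = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * BEAMLET_MM
        return rows, cols

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Beam unit vectors (w: source->isocenter, u: transverse, v: SI)."""
        th = np.deg2rad(self.gantry_angle_deg)
        # gantry 0: source on the anterior (-y) side of the patient
        src_dir = np.array([np.sin(th), -np.cos(th), 0.0])
        w = -src_dir
        u = np.array([np.cos(th), np.sin(th), 0.0])
        v = np.array([0.0, 0.0, 1.0])
        return w, u, v


@dataclass
class ScenarioSet:
    """Nominal + systematic translational setup-error scenarios.

    ``shifts_mm`` is (n, 3); the first row is the nominal (0,0,0) scenario.
    ``importance`` are non-negative weights summing to 1 (equal by default).
    """

    shifts_mm: np.ndarray
    importance: np.ndarray

    def __post_init__(self) -> None:
        self.shifts_mm = np.atleast_2d(np.asarray(self.shifts_mm, dtype=float))
        self.importance = np.asarray(self.importance, dtype=float)
        if self.shifts_mm.shape[1] != 3:
            raise ValueError("shifts must be (n, 3)")
        nominal = np.all(self.shifts_mm == 0.0, axis=1)
        if nominal.sum() != 1 or not nominal[0]:
            raise ValueError("exactly one nominal (0,0,0) scenario, listed first")
        if len(self.importance) != len(self.shifts_mm):
            raise ValueError("importance/shift length mismatch")
        if np.any(self.importance < 0) or not np.isclose(self.importance.sum(), 1.0):
            raise ValueError("importance weights must be >= 0 and sum to 1")

    def __len__(self) -> int:
        return len(self.shifts_mm)


_AXIS_INDEX = {"LR": 0, "AP": 1, "SI": 2}


def make_scenario_set(
    magnitude_mm: float, axes: Sequence[str] = ("LR", "AP", "SI")
) -> ScenarioSet:
    """Nominal plus +/-magnitude shifts along each requested patient axis."""
    if magnitude_mm <= 0 and axes:
        raise ValueError("shift magnitude must be positive")
    shifts = [np.zeros(3)]
    for name in ("LR", "AP", "SI"):
        if name in axes:
            for sign in (+1.0, -1.0):
                sh = np.zeros(3)
                sh[_AXIS_INDEX[name]] = sign * magnitude_mm
                shifts.append(sh)
    shifts = np.asarray(shifts)
    imp = np.full(len(shifts), 1.0 / len(shifts))
    return ScenarioSet(shifts, imp)


def nominal_only() -> ScenarioSet:
    return ScenarioSet(np.zeros((1, 3)), np.ones(1))


# ---------------------------------------------------------------------------
# depth dose and lateral profiles
# ---------------------------------------------------------------------------

def practical_range_mm(energy_mev: float) -> float:
    """Electron practical range R_p in water: E/2 in cm, i.e. 5*E mm."""
    return 5.0 * float(energy_mev)


def pdd_photon(depth_mm: np.ndarray) -> np.ndarray:
    """6 MV depth dose: quadratic buildup to d_max, then exponential."""
    d = np.asarray(depth_mm, dtype=float)
    t = np.clip(d / PHOTON_DMAX_MM, 0.0, 1.0)
    buildup = 2.0 * t - t * t
    atten = np.exp(-PHOTON_MU_PER_MM * np.maximum(d - PHOTON_DMAX_MM, 0.0))
    return buildup * atten


def pdd_electron(depth_mm: np.ndarray, energy_mev: float) -> np.ndarray:
    """Electron depth dose: plateau to 0.8 R_p, linear falloff to 0 at R_p.

    Energies >= 15 MeV carry a 2% bremsstrahlung tail (photon-like
    attenuation) that persists beyond the practical range.
    """
    d = np.asarray(depth_mm, dtype=float)
    rp = practical_range_mm(energy_mev)
    ramp = np.clip((rp - d) / (0.2 * rp), 0.0, 1.0)
    out = ramp
    if energy_mev >= BREMS_MIN_ENERGY_MEV:
        out = ramp + BREMS_FRACTION * np.exp(-BREMS_MU_PER_MM * d)
    return out


def lateral_profile(offset_mm: np.ndarray, sigma_mm: np.ndarray) -> np.ndarray:
    """Finite-beamlet lateral factor: Gaussian integrated over the 5 mm width.

    Difference of error functions; integrates to the beamlet width over the
    real line for any sigma, which keeps the kernel normalization
    independent of depth.
    """
    x = np.asarray(offset_mm, dtype=float)
    s = np.maximum(np.asarray(sigma_mm, dtype=float), 1e-6) * np.sqrt(2.0)
    half = BEAMLET_MM / 2.0
    return 0.5 * (erf((x + half) / s) - erf((x - half) / s))


# ---------------------------------------------------------------------------
# radiological depth
# ---------------------------------------------------------------------------

def radiological_depth(
    grid: VoxelGrid,
    entry_mm: Sequence[float],
    direction: Sequence[float],
    point_mm: Sequence[float],
    step_mm: float | None = None,
) -> float:
    """Water-equivalent depth: line integral of density from entry to point.

    Uniform ray stepping at half the minimum voxel spacing (midpoint rule,
    nearest-voxel density lookup; density outside the grid is zero).
    """
    entry = np.asarray(entry_mm, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if not np.isclose(np.linalg.norm(direction), 1.0, atol=1e-6):
        raise ValueError("direction must be a unit vector")
    point = np.asarray(point_mm, dtype=float)
    t_end = float(np.dot(point - entry, direction))
    if t_end < -1e-9:
        raise ValueError("point lies behind the entry along the ray")
    if step_mm is None:
        step_mm = min(grid.spacing_mm) / 2.0
    n = max(int(np.ceil(t_end / step_mm)), 0)
    if n == 0:
        return 0.0
    h = t_end / n
    t = (np.arange(n) + 0.5) * h
    pts = entry[None, :] + t[:, None] * direction[None, :]
    dens = _density_at(grid, pts)
    return float(np.sum(dens) * h)


def _density_at(grid: VoxelGrid, pts_mm: np.ndarray) -> np.ndarray:
    idx = np.rint(grid.world_to_index(pts_mm)).astype(np.int64)
    valid = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=-1)
    idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
    dens = grid.values[idx[..., 0], idx[..., 1], idx[..., 2]]
    return np.where(valid, dens, 0.0)


def _bulk_radiological_depth(
    grid: VoxelGrid, src: np.ndarray, points: np.ndarray, step_mm: float
) -> np.ndarray:
    """Radiological depth from the grid boundary to each point, rays from src.

    Vectorized over points: rays are clipped to the grid bounding box (slab
    method) and sampled at a fixed step; the tiny residual contribution of
    air (density 0.001) upstream of the body is included by construction.
    """
    points = np.atleast_2d(points)
    vec = points - src[None, :]
    dist = np.linalg.norm(vec, axis=1)
    dist = np.maximum(dist, 1e-9)
    dirs = vec / dist[:, None]

    lo = np.asarray(grid.origin_mm) - np.asarray(grid.spacing_mm) / 2.0
    hi = lo + np.asarray(grid.spacing_mm) * np.asarray(grid.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo[None, :] - src[None, :]) / dirs
        t2 = (hi[None, :] - src[None, :]) / dirs
    t_near = np.nanmax(np.minimum(t1, t2), axis=1)
    t_near = np.clip(t_near, 0.0, dist)

    seg = dist - t_near
    n_max = max(int(np.ceil(seg.max() / step_mm)), 1)
    k = (np.arange(n_max) + 0.5)[None, :] * step_mm  # (1, n)
    t = t_near[:, None] + k
    inside = t <= dist[:, None]
    pts = src[None, None, :] + t[..., None] * dirs[:, None, :]
    dens = _density_at(grid, pts)
    return np.sum(dens * inside, axis=1) * step_mm


# ---------------------------------------------------------------------------
# beamlet dose
# ---------------------------------------------------------------------------

def _field_geometry(field: Field):
    """Nominal source position and beam axes."""
    iso = np.asarray(field.isocenter_mm, dtype=float)
    w, u, v = field.axes()
    src = iso - SAD_MM * w
    return iso, src, w, u, v


def field_dose_matrix(
    field: Field,
    grid: VoxelGrid,
    shift_mm: Sequence[float],
    points_mm: np.ndarray,
    step_mm: float | None = None,
) -> np.ndarray:
    """Dense (n_points, n_beamlets) dose per unit weight for one scenario.

    Beamlets are enumerated row-major over ``jaw_rect``.  The per-point base
    term (depth dose, and inverse square for photons) is shared across
    beamlets; the lateral term is separable in the two isocenter-plane
    coordinates.

    The patient shift is applied as the isocenter-shift (static dose cloud)
    model: the nominal dose field is evaluated at the translated points,
    ``D_s(r) = D_0(r + s)`` exactly.  Dose deformation by surface curvature
    or heterogeneity under a shift is deliberately not modeled.
    """
    if step_mm is None:
        step_mm = min(grid.spacing_mm) / 2.0
    iso, src, w, u, v = _field_geometry(field)
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float)) + np.asarray(
        shift_mm, dtype=float
    )
    rel = pts - iso[None, :]
    z = rel @ w  # distance beyond the isocenter along the beam axis
    mag = SAD_MM / (SAD_MM + z)
    u_iso = (rel @ u) * mag
    v_iso = (rel @ v) * mag

    d_rad = _bulk_radiological_depth(grid, src, pts, step_mm)

    if field.modality == "photon":
        base = pdd_photon(d_rad) * mag * mag
        sigma = PHOTON_SIGMA0_MM + PHOTON_SIGMA_SLOPE * d_rad
    else:
        base = pdd_electron(d_rad, field.energy)
        sigma = ELECTRON_SIGMA0_MM + ELECTRON_SIGMA_SLOPE * d_rad

    rows_mm, cols_mm = field.beamlet_centers()
    r0, r1, c0, c1 = field.jaw_rect
    gv = lateral_profile(v_iso[:, None] - rows_mm[None, r0:r1], sigma[:, None])
    gu = lateral_profile(u_iso[:, None] - cols_mm[None, c0:c1], sigma[:, None])
    dose = base[:, None, None] * gv[:, :, None] * gu[:, None, :]
    return dose.reshape(pts.shape[0], -1)


def _single_beamlet_dose(
    field: Field, beamlet_index: int, grid: VoxelGrid, shift_mm: Sequence[float]
) -> np.ndarray:
    r0, r1, c0, c1 = field.jaw_rect
    if not (0 <= beamlet_index < field.n_beamlets):
        raise ValueError("beamlet index outside jaw_rect")
    xs, ys, zs = grid.voxel_centers()
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    out = np.empty(pts.shape[0])
    chunk = 8192
    for i in range(0, pts.shape[0], chunk):
        m = field_dose_matrix(field, grid, shift_mm, pts[i : i + chunk])
        out[i : i + chunk] = m[:, beamlet_index]
    return out.reshape(grid.shape)


def photon_beamlet_dose(
    field: Field, beamlet_index: int, grid: VoxelGrid, shift_mm=(0.0, 0.0, 0.0)
) -> np.ndarray:
    """Full-grid dose (per unit weight) of one photon beamlet."""
    if field.modality != "photon":
        raise ValueError("field is not a photon field")
    return _single_beamlet_dose(field, beamlet_index, grid, shift_mm)


def electron_beamlet_dose(
    field: Field, beamlet_index: int, grid: VoxelGrid, shift_mm=(0.0, 0.0, 0.0)
) -> np.ndarray:
    """Full-grid dose (per unit weight) of one electron beamlet."""
    if field.modality != "electron":
        raise ValueError("field is not an electron field")
    return _single_beamlet_dose(field, beamlet_index, grid, shift_mm)


# ---------------------------------------------------------------------------
# sampled voxel set and dose influence
# ---------------------------------------------------------------------------

@dataclass
class SampledVoxels:
    """Voxel subset the optimizer works on.

    All voxels of every non-body structure are included; the normal-tissue
    mask may be subsampled by a fixed stride per axis for tractability.
    ``structure_index[name]`` gives positions within the sampled arrays.
    """

    flat_indices: np.ndarray  # raveled grid indices, sorted, unique
    positions_mm: np.ndarray  # (n, 3) voxel-center world coordinates
    structure_index: dict[str, np.ndarray]
    normal_tissue_stride: int = 1

    @property
    def n(self) -> int:
        return len(self.flat_indices)


def sample_voxels(
    grid: VoxelGrid, structures: Sequence[Structure], normal_tissue_stride: int = 1
) -> SampledVoxels:
    shape = grid.shape
    selected = np.zeros(shape, dtype=bool)
    for s in structures:
        if s.role in ("body",):
            continue
        if s.role == "normal_tissue" and normal_tissue_stride > 1:
            stride_mask = np.zeros(shape, dtype=bool)
            st = normal_tissue_stride
            stride_mask[::st, ::st, ::st] = True
            selected |= s.mask & stride_mask
        else:
            selected |= s.mask
    flat = np.flatnonzero(selected)
    if flat.size == 0:
        raise ValueError("no structure voxels to sample")
    idx3 = np.stack(np.unravel_index(flat, shape), axis=1)
    pos = grid.index_to_world(idx3)
    lookup = np.full(int(np.prod(shape)), -1, dtype=np.int64)
    lookup[flat] = np.arange(flat.size)
    structure_index: dict[str, np.ndarray] = {}
    for s in structures:
        sflat = np.flatnonzero(s.mask)
        loc = lookup[sflat]
        structure_index[s.name] = loc[loc >= 0]
    return SampledVoxels(flat, pos, structure_index, normal_tissue_stride)


@dataclass
class DoseInfluence:
    """Per (field, scenario) beamlet dose matrices on the sampled voxel set.

    ``matrices[f][s]`` is a CSC matrix of shape (n_sampled_voxels,
    n_beamlets) holding dose per unit aperture weight, for field index ``f``
    and scenario index ``s``.  CSC keeps per-beamlet column slicing cheap,
    which is what aperture dose assembly and annealing moves need.
    """

    fields: list[Field]
    scenarios: ScenarioSet
    voxels: SampledVoxels
    matrices: list[list[sparse.csc_matrix]]
    _col_cache: dict = dc_field(default_factory=dict, repr=False, compare=False)

    def matrix(self, field_index: int, scenario_index: int) -> sparse.csc_matrix:
        return self.matrices[field_index][scenario_index]

    def beamlet_column(self, field_index: int, beamlet: int) -> np.ndarray:
        """Dense (n_scen, n_vox) dose column of one beamlet, cached.

        The annealing moves touch single beamlets repeatedly; direct CSC
        index arithmetic plus caching keeps them cheap.
        """
        key = (field_index, beamlet)
        col = self._col_cache.get(key)
        if col is None:
            n_scen = len(self.scenarios)
            col = np.zeros((n_scen, self.voxels.n))
            for s in range(n_scen):
                m = self.matrices[field_index][s]
                lo, hi = m.indptr[beamlet], m.indptr[beamlet + 1]
                col[s, m.indices[lo:hi]] = m.data[lo:hi]
            self._col_cache[key] = col
        return col


def build_dose_influence(
    fields: Sequence[Field],
    grid: VoxelGrid,
    structures: Sequence[Structure],
    scenarios: ScenarioSet,
    normal_tissue_stride: int = 1,
    sparse_threshold: float = 1e-4,
) -> DoseInfluence:
    """Beamlet dose matrices for every field and every scenario.

    Entries below ``sparse_threshold`` of each beamlet's maximum are dropped
    before sparse storage; the result is deterministic.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("no fields given")
    vox = sample_voxels(grid, structures, normal_tissue_stride)
    matrices: list[list[sparse.csr_matrix]] = []
    for f in fields:
        per_scen = []
        for s in range(len(scenarios)):
            dense = field_dose_matrix(f, grid, scenarios.shifts_mm[s], vox.positions_mm)
            peak = dense.max(axis=0)
            cut = sparse_threshold * np.where(peak > 0, peak, 1.0)
            dense[dense < cut[None, :]] = 0.0
            per_scen.append(sparse.csc_matrix(dense))
        matrices.append(per_scen)
    return DoseInfluence(fields, scenarios, vox, matrices)


def fit_field_grid(
    field: Field, grid: VoxelGrid, target: Structure, margin_mm: float = 10.0
) -> Field:
    """Size a field's beamlet grid to cover the target projection + margin.

    Projects the target voxel centers onto the isocenter plane (beam's-eye
    view) and returns a copy of the field with n_rows/n_cols covering the
    bounding box expanded by ``margin_mm`` on each side.
    """
    idx3 = np.stack(np.nonzero(target.mask), axis=1)
    if idx3.size == 0:
        raise ValueError("target structure is empty")
    pts = grid.index_to_world(idx3)
    iso, src, w, u, v = _field_geometry(field)
    rel = pts - iso[None, :]
    magn = SAD_MM / (SAD_MM + rel @ w)
    u_iso = (rel @ u) * magn
    v_iso = (rel @ v) * magn
    half_u = max(abs(u_iso.min()), abs(u_iso.max())) + margin_mm
    half_v = max(abs(v_iso.min()), abs(v_iso.max())) + margin_mm
    n_cols = 2 * int(np.ceil(half_u / BEAMLET_MM))
    n_rows = 2 * int(np.ceil(half_v / BEAMLET_MM))
    return Field(
        id=field.id,
        modality=field.modality,
        energy=field.energy,
        gantry_angle_deg=field.gantry_angle_deg,
        isocenter_mm=field.isocenter_mm,
        n_rows=max(n_rows, 2),
        n_cols=max(n_cols, 2),
        ssd_mm=field.ssd_mm,
    )
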