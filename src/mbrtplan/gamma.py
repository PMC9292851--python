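"""2D gamma analysis of planar dose distributions (TG-218 style).

gamma(r_ref) = min over evaluated points r_e of
    sqrt( (D_e(r_e) - D_ref(r_ref))^2 / (dose_pct% * D_norm)^2
        + |r_e - r_ref|^2 / dta_mm^2 )

with global normalization D_norm = max of the reference plane (the TG-218
default), a dose threshold excluding low-dose reference pixels from both
the map and the passing-rate denominator, and the continuous minimum
approximated by bilinear resampling of the evaluated plane to a fine grid
(default 0.5 mm) searched within a radius of 3 x DTA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geometry import VoxelGrid


@dataclass
class PlanarDose:
    """2D dose plane: values (n0, n1), pixel spacing and origin in mm."""

    values: np.ndarray
    spacing_mm: tuple[float, float]
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("planar dose must be 2D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("pixel spacing must be positive")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.values.shape[a])
            for a in range(2)
        )


@dataclass
class GammaResult:
    gamma: np.ndarray  # per reference pixel; NaN where below threshold
    passing_rate_pct: float
    criteria: dict

    @property
    def n_evaluated(self) -> int:
        return int(np.sum(~np.isnan(self.gamma)))


def gamma_map(
    reference: PlanarDose,
    evaluated: PlanarDose,
    dose_pct: float = 3.0,
    dta_mm: float = 2.0,
    threshold_pct: float = 10.0,
    resample_mm: float = 0.5,
    search_factor: float = 3.0,
) -> GammaResult:
    """Gamma index of an evaluated plane against a reference plane.

    Reference pixels below ``threshold_pct`` of the reference maximum are
    excluded from the map and the passing-rate denominator.
    """
    ref_ax0, ref_ax1 = reference.axes()
    ev_ax0, ev_ax1 = evaluated.axes()
    if (
        ref_ax0[-1] < ev_ax0[0]
        or ev_ax0[-1] < ref_ax0[0]
        or ref_ax1[-1] < ev_ax1[0]
        or ev_ax1[-1] < ref_ax1[0]
    ):
        raise ValueError("reference and evaluated planes do not overlap")

    d_norm = float(reference.values.max())
    if d_norm <= 0:
        raise ValueError("reference plane has no dose")
    dd_abs = dose_pct / 100.0 * d_norm
    cutoff = threshold_pct / 100.0 * d_norm

    interp = RegularGridInterpolator(
        (ev_ax0, ev_ax1), evaluated.values, method="linear", bounds_error=False,
        fill_value=np.nan,
    )

    mask = reference.values >= cutoff
    pix0, pix1 = np.nonzero(mask)
    p0 = ref_ax0[pix0]
    p1 = ref_ax1[pix1]
    d_ref = reference.values[pix0, pix1]

    radius = search_factor * dta_mm
    n_off = int(np.floor(radius / resample_mm))
    offs = np.arange(-n_off, n_off + 1) * resample_mm
    best = np.full(p0.shape, np.inf)
    for o0 in offs:
        for o1 in offs:
            r2 = o0 * o0 + o1 * o1
            if r2 > radius * radius + 1e-12:
                continue
            vals = interp(np.column_stack([p0 + o0, p1 + o1]))
            g2 = (vals - d_ref) ** 2 / dd_abs**2 + r2 / dta_mm**2
            np.fmin(best, g2, out=best)  # fmin ignores NaN from outside points
    gamma_vals = np.sqrt(best)

    gmap = np.full(reference.values.shape, np.nan)
    gmap[pix0, pix1] = gamma_vals
    finite = np.isfinite(gamma_vals)
    rate = 100.0 * float(np.mean(gamma_vals[finite] <= 1.0)) if finite.any() else 0.0
    return GammaResult(
        gmap,
        rate,
        {
            "dose_pct": dose_pct,
            "dta_mm": dta_mm,
            "threshold_pct": threshold_pct,
            "normalization": "global",
            "resample_mm": resample_mm,
        },
    )


def extract_plane(dose_grid: VoxelGrid, axis: int, index_or_mm, in_mm: bool = False) -> PlanarDose:
    """Slice a 3D dose grid perpendicular to ``axis`` at a voxel index or mm.

    Spacing and origin of the remaining two axes are propagated; the
    extracted plane reproduces stored voxel values exactly at voxel
    centers.
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    if in_mm:
        frac = (float(index_or_mm) - dose_grid.origin_mm[axis]) / dose_grid.spacing_mm[axis]
        index = int(np.rint(frac))
    else:
        index = int(index_or_mm)
    if not (0 <= index < dose_grid.shape[axis]):
        raise ValueError("plane outside the grid")
    sl = [slice(None)] * 3
    sl[axis] = index
    keep = [a for a in range(3) if a != axis]
    return PlanarDose(
        dose_grid.values[tuple(sl)],
        spacing_mm=tuple(dose_grid.spacing_mm[a] for a in keep),
        origin_mm=tuple(dose_grid.origin_mm[a] for a in keep),
    )
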