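"""DVHs, dose-volume metrics, homogeneity index and robustness reports.

Point metrics (D_x%, V_x, D_mean) are computed on raw per-voxel doses, not
on binned DVH curves: D_x% uses the nearest-rank quantile (the dose
exceeded-or-met by exactly the hottest x% of voxels), which is exact and
bin-free.  Binned cumulative DVHs exist for plotting and export only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .finalize import Plan
from .geometry import Structure, VoxelGrid


def _structure_doses(dose, structure=None) -> np.ndarray:
    """Accept a 1D dose array, or a 3D grid/array plus a Structure mask."""
    if structure is not None:
        values = dose.values if isinstance(dose, VoxelGrid) else np.asarray(dose)
        return values[structure.mask]
    return np.asarray(dose, dtype=float).ravel()


@dataclass
class DVHCurve:
    structure: str
    dose_gy: np.ndarray  # bin edges, ascending from 0
    volume_fraction: np.ndarray  # cumulative, non-increasing, starts at 1


def cumulative_dvh(dose, structure=None, bin_gy: float = 0.1, name: str = "") -> DVHCurve:
    """Cumulative DVH: V(d) = fraction of structure voxels with dose >= d."""
    if bin_gy <= 0:
        raise ValueError("bin width must be positive")
    d = _structure_doses(dose, structure)
    if d.size == 0:
        raise ValueError("empty structure")
    edges = np.arange(0.0, d.max() + 2 * bin_gy, bin_gy)
    vol = (d[None, :] >= edges[:, None]).mean(axis=1)
    label = structure.name if structure is not None else name
    return DVHCurve(label, edges, vol)


def dose_at_volume(dose, x_percent: float, structure=None) -> float:
    """D_x%: nearest-rank dose exceeded-or-met by the hottest x% of voxels."""
    if not (0.0 < x_percent <= 100.0):
        raise ValueError("x must be in (0, 100]")
    d = np.sort(_structure_doses(dose, structure))[::-1]
    k = max(int(np.floor(d.size * x_percent / 100.0)), 1)
    return float(d[k - 1])


def volume_at_dose(dose, level_gy: float, structure=None) -> float:
    """V at a dose level, in percent of the structure volume."""
    d = _structure_doses(dose, structure)
    return float(100.0 * np.mean(d >= level_gy))


def mean_dose(dose, structure=None) -> float:
    return float(_structure_doses(dose, structure).mean())


def hi_95_107(dose, prescription_gy: float, structure=None) -> float:
    """Homogeneity index HI_95/107 = V95% - V107% (percentage points)."""
    d = _structure_doses(dose, structure)
    v95 = 100.0 * np.mean(d >= 0.95 * prescription_gy)
    v107 = 100.0 * np.mean(d >= 1.07 * prescription_gy)
    return float(v95 - v107)


# ---------------------------------------------------------------------------
# metric specs and the robustness report
# ---------------------------------------------------------------------------

@dataclass
class Metric:
    """One report row: a metric evaluated on one structure.

    kind: "Dmean" | "Dx" (needs x) | "V" (needs level_gy or level_pct)
          | "HI_95_107" (needs prescription).
    """

    structure: str
    kind: str
    x: float | None = None
    level_gy: float | None = None
    level_pct: float | None = None

    def label(self) -> str:
        if self.kind == "Dmean":
            return f"{self.structure} D_mean (Gy)"
        if self.kind == "Dx":
            return f"{self.structure} D_{self.x:g}% (Gy)"
        if self.kind == "V":
            lvl = f"{self.level_pct:g}%" if self.level_pct is not None else f"{self.level_gy:g}Gy"
            return f"{self.structure} V_{lvl} (%)"
        return f"{self.structure} HI_95/107 (%)"

    def evaluate(self, doses: np.ndarray, prescription_gy: float) -> float:
        if self.kind == "Dmean":
            return float(doses.mean())
        if self.kind == "Dx":
            return dose_at_volume(doses, self.x)
        if self.kind == "V":
            level = (
                self.level_gy
                if self.level_gy is not None
                else self.level_pct / 100.0 * prescription_gy
            )
            return volume_at_dose(doses, level)
        if self.kind == "HI_95_107":
            return hi_95_107(doses, prescription_gy)
        raise ValueError(f"unknown metric kind {self.kind!r}")


@dataclass
class RobustnessReport:
    """Per-metric per-scenario values with mean +/- SD, plus MU summaries.

    SD across scenarios is the population SD over all scenario values
    (nominal included).
    """

    table: pd.DataFrame  # rows: metrics, columns: scenario values + mean + sd
    total_mu: float
    electron_mu_fraction_pct: float
    electron_ctv_dmean_fraction_pct: float
    prescription_gy: float


def robustness_report(
    plan: Plan,
    metrics: Sequence[Metric],
    prescription_gy: float,
    target_structure: str = "ctv",
) -> RobustnessReport:
    """Evaluate every metric on every scenario dose of a finalized plan."""
    n_scen = plan.scenario_dose.shape[0]
    rows = {}
    for m in metrics:
        idx = plan.influence.voxels.structure_index[m.structure]
        vals = [
            m.evaluate(plan.scenario_dose[s, idx], prescription_gy)
            for s in range(n_scen)
        ]
        rows[m.label()] = vals
    tbl = pd.DataFrame(rows).T
    tbl.columns = [f"scenario_{s}" for s in range(n_scen)]
    tbl["mean"] = tbl.iloc[:, :n_scen].mean(axis=1)
    tbl["sd"] = tbl.iloc[:, :n_scen].std(axis=1, ddof=0)

    mu = plan.mu
    total_mu = float(mu.sum())
    is_electron = np.array(
        [plan.influence.fields[a.field_index].modality == "electron" for a in plan.apertures]
    )
    e_mu = float(mu[is_electron].sum()) if len(mu) else 0.0
    e_mu_frac = 100.0 * e_mu / total_mu if total_mu > 0 else 0.0

    ctv_idx = plan.influence.voxels.structure_index[target_structure]
    total_mean = float(plan.scenario_dose[0, ctv_idx].mean())
    e_mean = 0.0
    for a, ud, el in zip(plan.apertures, plan.aperture_unit_dose, is_electron):
        if el:
            e_mean += a.weight * float(ud[0, ctv_idx].mean())
    e_dose_frac = 100.0 * e_mean / total_mean if total_mean > 0 else 0.0

    return RobustnessReport(tbl, total_mu, e_mu_frac, e_dose_frac, prescription_gy)


def mu_weighted_energy(plan: Plan) -> tuple[float, float]:
    """(MU-weighted mean electron energy in MeV, energy with the most MU)."""
    per_energy: dict[float, float] = {}
    for a in plan.apertures:
        fld = plan.influence.fields[a.field_index]
        if fld.modality == "electron":
            per_energy[fld.energy] = per_energy.get(fld.energy, 0.0) + a.weight
    total = sum(per_energy.values())
    if total <= 0:
        raise ValueError("plan has no electron apertures with MU")
    mean_e = sum(e * mu for e, mu in per_energy.items()) / total
    modal_e = max(sorted(per_energy), key=lambda e: per_energy[e])
    return float(mean_e), float(modal_e)
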