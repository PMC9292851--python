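"""Dose objective: one-sided quadratic penalties and their robust expectation.

The objective is the de-facto standard of direct aperture optimization: a
weighted sum of one-sided quadratic dose penalties,

    F(D) = sum_t (w_t / |V_t|) * sum_{i in A_t} (D_i - d_t)^2,

where the active set A_t holds the underdosed voxels (``min_dose``), the
overdosed voxels (``max_dose``), or — for dose-volume constraints
(``dose_volume_upper``) — the voxels exceeding the dose level after
exempting the hottest fraction that the constraint allows (DVH-sorting
heuristic).  ``mean_dose_upper`` penalizes w_t * (mean(D) - d_t)_+^2.

The robust (stochastic) objective is the importance-weighted expectation of
F over the setup-error scenarios; with a nominal-only scenario set it
reduces *exactly* (bit-for-bit) to the plain objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .beams import ScenarioSet

KINDS = ("min_dose", "max_dose", "mean_dose_upper", "dose_volume_upper")


@dataclass
class ObjectiveTerm:
    structure: str
    kind: str
    dose_level_gy: float
    weight: float
    volume_fraction: float | None = None  # dose_volume_upper only

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError("term weight must be positive")
        if self.kind == "dose_volume_upper":
            if self.volume_fraction is None or not (0.0 <= self.volume_fraction <= 1.0):
                raise ValueError("dose_volume_upper needs volume_fraction in [0, 1]")
        elif self.volume_fraction is not None:
            raise ValueError("volume_fraction only applies to dose_volume_upper")


@dataclass
class ObjectiveSpec:
    terms: list[ObjectiveTerm]
    prescription_gy: float
    target_structure: str

    def __post_init__(self) -> None:
        if not self.target_structure:
            raise ValueError("a target normalization structure is required")


class ObjectiveFunction:
    """Objective bound to a voxel-index mapping, vectorized over scenarios.

    ``structure_index`` maps structure names to integer index arrays into
    the dose vector (e.g. the sampled voxel set of the dose influence).
    """

    def __init__(self, spec: ObjectiveSpec, structure_index: Mapping[str, np.ndarray]):
        self.spec = spec
        self._terms = []
        for t in spec.terms:
            if t.structure not in structure_index:
                raise KeyError(f"objective references unknown structure {t.structure!r}")
            idx = np.asarray(structure_index[t.structure], dtype=np.int64)
            if idx.size == 0:
                raise ValueError(f"structure {t.structure!r} has no sampled voxels")
            self._terms.append((t, idx))

    # -- active sets --------------------------------------------------------

    @staticmethod
    def _dv_active(dsub: np.ndarray, term: ObjectiveTerm) -> np.ndarray:
        """Indices (into the structure's voxels) penalized by a DV term.

        The hottest floor(vf * n) voxels are exempt; remaining voxels above
        the dose level are active.  Stable argsort keeps this deterministic.
        """
        n = dsub.shape[-1]
        allowed = int(np.floor(term.volume_fraction * n))
        order = np.argsort(-dsub, kind="stable")
        candidates = order[allowed:]
        return candidates[dsub[candidates] > term.dose_level_gy]

    def freeze_dv(self, doses: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
        """Freeze dose-volume active sets at the given per-scenario doses.

        ``doses`` is (n_scen, n_vox); returns {(term_i, scen_i): active}.
        """
        doses = np.atleast_2d(doses)
        frozen: dict[tuple[int, int], np.ndarray] = {}
        for ti, (t, idx) in enumerate(self._terms):
            if t.kind != "dose_volume_upper":
                continue
            for si in range(doses.shape[0]):
                frozen[(ti, si)] = self._dv_active(doses[si, idx], t)
        return frozen

    # -- value and gradient --------------------------------------------------

    def value(self, dose: np.ndarray, frozen=None, scenario: int = 0) -> float:
        # Delegates to value_many so the single-scenario and stacked paths
        # share one code path (and agree bit-for-bit).
        if frozen is not None and scenario != 0:
            frozen = {(ti, 0): act for (ti, si), act in frozen.items() if si == scenario}
        return float(self.value_many(dose[None, :], frozen)[0])

    def value_many(self, doses: np.ndarray, frozen=None) -> np.ndarray:
        """Objective per scenario for stacked doses of shape (n_scen, n_vox)."""
        doses = np.atleast_2d(doses)
        ns = doses.shape[0]
        out = np.zeros(ns)
        for ti, (t, idx) in enumerate(self._terms):
            d = doses[:, idx]
            n = d.shape[1]
            if t.kind == "min_dose":
                r = np.minimum(d - t.dose_level_gy, 0.0)
                out += t.weight / n * np.einsum("ij,ij->i", r, r)
            elif t.kind == "max_dose":
                r = np.maximum(d - t.dose_level_gy, 0.0)
                out += t.weight / n * np.einsum("ij,ij->i", r, r)
            elif t.kind == "mean_dose_upper":
                excess = np.maximum(d.mean(axis=1) - t.dose_level_gy, 0.0)
                out += t.weight * excess * excess
            else:
                for si in range(ns):
                    if frozen is not None and (ti, si) in frozen:
                        active = frozen[(ti, si)]
                    else:
                        active = self._dv_active(d[si], t)
                    r = d[si, active] - t.dose_level_gy
                    out[si] += t.weight / n * float(r @ r)
        return out

    def gradient(self, dose: np.ndarray, frozen=None, scenario: int = 0) -> np.ndarray:
        if frozen is not None and scenario != 0:
            frozen = {(ti, 0): act for (ti, si), act in frozen.items() if si == scenario}
        return self.gradient_many(dose[None, :], frozen)[0]

    def gradient_many(self, doses: np.ndarray, frozen=None) -> np.ndarray:
        """dF/dD per scenario for stacked doses of shape (n_scen, n_vox)."""
        doses = np.atleast_2d(doses)
        ns = doses.shape[0]
        g = np.zeros_like(doses, dtype=float)
        for ti, (t, idx) in enumerate(self._terms):
            d = doses[:, idx]
            n = d.shape[1]
            if t.kind == "min_dose":
                g[:, idx] += 2.0 * t.weight / n * np.minimum(d - t.dose_level_gy, 0.0)
            elif t.kind == "max_dose":
                g[:, idx] += 2.0 * t.weight / n * np.maximum(d - t.dose_level_gy, 0.0)
            elif t.kind == "mean_dose_upper":
                excess = np.maximum(d.mean(axis=1) - t.dose_level_gy, 0.0)
                g[:, idx] += (2.0 * t.weight / n) * excess[:, None]
            else:
                for si in range(ns):
                    if frozen is not None and (ti, si) in frozen:
                        active = frozen[(ti, si)]
                    else:
                        active = self._dv_active(d[si], t)
                    g[si, idx[active]] += (
                        2.0 * t.weight / n * (d[si, active] - t.dose_level_gy)
                    )
        return g


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def evaluate(
    dose: np.ndarray, spec: ObjectiveSpec, structure_index: Mapping[str, np.ndarray]
) -> float:
    """Plain (single-scenario) objective value; always >= 0."""
    return ObjectiveFunction(spec, structure_index).value(np.asarray(dose, dtype=float))


def voxel_gradient(
    dose: np.ndarray, spec: ObjectiveSpec, structure_index: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Analytic dF/dD_i; zero outside every active set."""
    return ObjectiveFunction(spec, structure_index).gradient(np.asarray(dose, dtype=float))


def robust_value(
    doses: Sequence[np.ndarray],
    spec: ObjectiveSpec,
    scenarios: ScenarioSet,
    structure_index: Mapping[str, np.ndarray],
) -> float:
    """Importance-weighted expectation of the objective over scenarios."""
    if len(doses) != len(scenarios):
        raise ValueError("one dose per scenario required")
    fn = ObjectiveFunction(spec, structure_index)
    total = 0.0
    for s, dose in enumerate(doses):
        total += scenarios.importance[s] * fn.value(np.asarray(dose, dtype=float))
    return total


def robust_voxel_gradients(
    doses: Sequence[np.ndarray],
    spec: ObjectiveSpec,
    scenarios: ScenarioSet,
    structure_index: Mapping[str, np.ndarray],
) -> list[np.ndarray]:
    """Per-scenario voxel gradients scaled by scenario importance."""
    if len(doses) != len(scenarios):
        raise ValueError("one dose per scenario required")
    fn = ObjectiveFunction(spec, structure_index)
    return [
        scenarios.importance[s] * fn.gradient(np.asarray(doses[s], dtype=float))
        for s in range(len(scenarios))
    ]
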