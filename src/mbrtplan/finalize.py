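"""Final aperture dose with collimator transmission, re-weighting, normalization.

The optimizer works on beamlet sums that ignore the collimator; the final
aperture dose adds a transmission term through the closed-but-within-jaw
MLC area (photon fields only — electron apertures at shortened SSD are
treated as fully blocking).  The discrepancy between the two dose sets is
what the final robust weight re-optimization corrects, mirroring the role
of the final-dose recalculation step in clinical DAO pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .beams import DoseInfluence, ScenarioSet
from .dao import Aperture, AperturePool, DAOConfig, _Evaluator, optimize_weights
from .objective import ObjectiveFunction, ObjectiveSpec

PHOTON_MLC_TRANSMISSION = 0.015
ELECTRON_MLC_TRANSMISSION = 0.0


@dataclass
class Plan:
    """Final apertures (MU), per-scenario sampled dose, and provenance."""

    apertures: list[Aperture]
    influence: DoseInfluence
    scenario_dose: np.ndarray  # (n_scen, n_vox) in Gy
    aperture_unit_dose: list[np.ndarray]  # (n_scen, n_vox) incl. transmission
    normalization: dict | None = None
    provenance: dict = dc_field(default_factory=dict)

    @property
    def mu(self) -> np.ndarray:
        return np.array([a.weight for a in self.apertures])

    def structure_dose(self, name: str, scenario: int = 0) -> np.ndarray:
        idx = self.influence.voxels.structure_index[name]
        return self.scenario_dose[scenario, idx]

    def recompute_dose(self) -> None:
        self.scenario_dose = np.zeros_like(self.scenario_dose)
        for a, ud in zip(self.apertures, self.aperture_unit_dose):
            self.scenario_dose += a.weight * ud


def aperture_dose(
    aperture: Aperture,
    influence: DoseInfluence,
    scenario: int,
    transmission: float | None = None,
) -> np.ndarray:
    """Unit-weight aperture dose for one scenario, with MLC transmission.

    Open beamlets contribute fully; closed beamlets inside the jaws
    contribute ``transmission`` times their dose (default 1.5% for photon
    fields, 0 for electron fields).
    """
    f = aperture.field_index
    fld = influence.fields[f]
    if transmission is None:
        transmission = (
            PHOTON_MLC_TRANSMISSION if fld.modality == "photon" else ELECTRON_MLC_TRANSMISSION
        )
    if not (0.0 <= transmission < 1.0):
        raise ValueError("transmission must be in [0, 1)")
    m = influence.matrix(f, scenario)
    open_b = aperture.open_beamlets(fld.jaw_rect)
    open_dose = (
        np.asarray(m[:, open_b].sum(axis=1)).ravel()
        if open_b.size
        else np.zeros(influence.voxels.n)
    )
    if transmission == 0.0:
        return open_dose
    total = np.asarray(m.sum(axis=1)).ravel()
    return open_dose + transmission * (total - open_dose)


def _aperture_unit_doses(
    pool_apertures: list[Aperture],
    influence: DoseInfluence,
    transmission_photon: float,
    transmission_electron: float,
) -> list[np.ndarray]:
    n_scen = len(influence.scenarios)
    out = []
    for a in pool_apertures:
        tr = (
            transmission_photon
            if influence.fields[a.field_index].modality == "photon"
            else transmission_electron
        )
        out.append(
            np.stack([aperture_dose(a, influence, s, tr) for s in range(n_scen)])
        )
    return out


def finalize_plan(
    pool: AperturePool,
    influence: DoseInfluence,
    spec: ObjectiveSpec,
    opt_scenarios: ScenarioSet | None,
    cfg: DAOConfig,
    transmission_photon: float = PHOTON_MLC_TRANSMISSION,
    transmission_electron: float = ELECTRON_MLC_TRANSMISSION,
    provenance: dict | None = None,
) -> Plan:
    """Recompute aperture doses with transmission and re-optimize weights.

    The final weight optimization runs under the same objective mode as the
    planning run (robust expectation, or nominal-only when
    ``opt_scenarios`` is None); the plan's scenario doses are then summed
    for *all* scenarios of the influence so every plan can be evaluated
    under the full error-scenario set.
    """
    unit = _aperture_unit_doses(
        pool.apertures, influence, transmission_photon, transmission_electron
    )
    plan = Plan(
        apertures=[Aperture(a.field_index, a.field_id, list(a.rows), a.weight) for a in pool.apertures],
        influence=influence,
        scenario_dose=np.zeros((len(influence.scenarios), influence.voxels.n)),
        aperture_unit_dose=unit,
        provenance=provenance or {},
    )
    final_weight_opt(plan, spec, opt_scenarios, cfg)
    plan.recompute_dose()
    return plan


def final_weight_opt(
    plan: Plan,
    spec: ObjectiveSpec,
    opt_scenarios: ScenarioSet | None,
    cfg: DAOConfig,
) -> Plan:
    """Robust deterministic weight re-optimization on aperture-level doses."""
    if not plan.apertures:
        return plan
    objfn = ObjectiveFunction(spec, plan.influence.voxels.structure_index)
    ev = _Evaluator(objfn, opt_scenarios)
    tmp = AperturePool(ev.n_scen, plan.influence.voxels.n)
    for a, ud in zip(plan.apertures, plan.aperture_unit_dose):
        tmp.add(a, ud[: ev.n_scen])
    optimize_weights(tmp, ev, cfg)
    plan.recompute_dose()
    return plan


def normalize(plan: Plan, mode: str, structure: str, level_gy: float) -> Plan:
    """Scale all MUs so the nominal-scenario D_mode of ``structure`` = level.

    ``mode`` is "D50" or "D95"; scenario doses scale by the same factor, so
    the operation is exactly linear and idempotent.
    """
    from .evaluation import dose_at_volume

    if mode not in ("D50", "D95"):
        raise ValueError("normalization mode must be D50 or D95")
    x = 50.0 if mode == "D50" else 95.0
    doses = plan.structure_dose(structure, scenario=0)
    current = dose_at_volume(doses, x)
    if current <= 0.0:
        raise ValueError(f"zero dose in normalization structure {structure!r}")
    factor = level_gy / current
    for a in plan.apertures:
        a.weight *= factor
    plan.scenario_dose *= factor
    plan.normalization = {
        "mode": mode,
        "structure": structure,
        "level_gy": level_gy,
        "factor": factor,
    }
    return plan
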