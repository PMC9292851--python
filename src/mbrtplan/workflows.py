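"""End-to-end planning workflows: robust and PTV-based plans, evaluation.

``plan_case`` is the whole pipeline: synthetic case -> margins -> fields ->
scenario-shifted dose influence -> hybrid DAO -> finalization (collimator
transmission + final weight optimization) -> normalization -> scenario-wise
evaluation.  In robust mode the optimizer minimizes the scenario
expectation with the CTV as target; in PTV mode it optimizes the nominal
scenario only with the PTV (CTV + margin, cropped from the body surface)
as target and PRV structures standing in for the OARs, and the error
scenarios are used purely for post-hoc evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as mio
from .beams import (
    Field,
    ScenarioSet,
    build_dose_influence,
    field_dose_matrix,
    fit_field_grid,
    make_scenario_set,
    nominal_only,
)
from .config import CaseConfig
from .dao import AperturePool, run_hybrid_dao
from .evaluation import Metric, RobustnessReport, robustness_report
from .finalize import Plan, finalize_plan, normalize
from .geometry import (
    Structure,
    VoxelGrid,
    crop_from_body,
    expand_margin,
    make_normal_tissue,
    make_synthetic_case,
)
from .objective import ObjectiveSpec, ObjectiveTerm


@dataclass
class PreparedCase:
    grid: VoxelGrid
    structures: dict[str, Structure]
    fields: list[Field]
    scenarios: ScenarioSet
    objective: ObjectiveSpec
    target: str  # normalization structure


@dataclass
class PlanResult:
    plan: Plan
    pool: AperturePool
    report: RobustnessReport
    log: list[dict]
    prepared: PreparedCase
    config: CaseConfig


def _oar_tolerance_fractions(gap_mm: float) -> tuple[float, float]:
    """(mean, max) tolerance as fractions of the prescription, graded by
    the OAR's gap to the target.

    Target coverage outranks OAR sparing: an organ abutting a full-dose
    target cannot be held to a low mean dose without sacrificing coverage,
    so nearby OARs get lenient, achievable levels and distant ones tight
    levels (the clinical priority ordering).
    """
    if gap_mm < 5.0:
        return 0.35, 0.95
    if gap_mm < 20.0:
        return 0.20, 0.70
    return 0.12, 0.50


def default_objective_terms(
    target: str,
    oar_gaps_mm: dict[str, float],
    rx: float,
    oar_suffix: str = "",
) -> list[ObjectiveTerm]:
    """Built-in objective template producing clinically shaped plans.

    Target coverage window 0.98-1.05 of the prescription at dominant
    weight, per-OAR mean/max sparing with distance-graded tolerances, and
    a loose normal-tissue cap.  Values are configuration, not claims.
    """
    terms = [
        ObjectiveTerm(target, "min_dose", 0.98 * rx, 100.0),
        ObjectiveTerm(target, "max_dose", 1.05 * rx, 50.0),
    ]
    for name, gap in oar_gaps_mm.items():
        f_mean, f_max = _oar_tolerance_fractions(gap)
        terms.append(ObjectiveTerm(name + oar_suffix, "mean_dose_upper", f_mean * rx, 8.0))
        terms.append(ObjectiveTerm(name + oar_suffix, "max_dose", f_max * rx, 8.0))
    terms.append(ObjectiveTerm("normal_tissue", "max_dose", 0.80 * rx, 5.0))
    terms.append(ObjectiveTerm("normal_tissue", "mean_dose_upper", 0.06 * rx, 3.0))
    return terms


def make_fields(cfg: CaseConfig, grid: VoxelGrid, jaw_target: Structure) -> list[Field]:
    """Photon fields at equally spaced angles + one electron field per
    direction/energy combination, beamlet grids fitted to the target.

    All beams are isocentric at the target centroid (rounded to mm), which
    keeps the fitted beamlet grids compact.
    """
    idx3 = np.stack(np.nonzero(jaw_target.mask), axis=1)
    iso = tuple(np.round(grid.index_to_world(idx3).mean(axis=0), 0))
    arr = cfg.fields
    fields: list[Field] = []
    for k in range(arr.n_photon_fields):
        ang = arr.photon_start_angle_deg + 360.0 * k / arr.n_photon_fields
        fields.append(Field(f"ph{k:02d}_g{ang:.0f}", "photon", 6.0, ang, isocenter_mm=iso))
    for d, (ang, ssd) in enumerate(zip(arr.electron_gantry_angles_deg, arr.electron_ssd_mm)):
        for e in arr.electron_energies_mev:
            fields.append(
                Field(f"el{d}_g{ang:.0f}_E{e:g}", "electron", e, ang, isocenter_mm=iso, ssd_mm=ssd)
            )
    return [fit_field_grid(f, grid, jaw_target, arr.jaw_margin_mm) for f in fields]


def prepare_case(cfg: CaseConfig) -> PreparedCase:
    grid, struct_list = make_synthetic_case(cfg.case)
    structures = {s.name: s for s in struct_list}
    body = structures["body"]
    ctv = structures["ctv"]
    oar_names = [s.name for s in struct_list if s.role == "oar"]
    rx = cfg.prescription.level_gy

    scenarios = make_scenario_set(cfg.scenario_magnitude_mm, cfg.scenario_axes) if cfg.scenario_axes else nominal_only()

    if cfg.mode == "robust":
        # normal tissue excludes CTV and OARs; target = CTV
        target = "ctv"
        jaw_target = expand_margin(ctv, grid, cfg.scenario_magnitude_mm)
        oar_suffix = ""
    else:
        ptv = expand_margin(ctv, grid, cfg.ptv_margin_mm)
        ptv = crop_from_body(ptv, body, grid, cfg.body_crop_mm)
        ptv.name, ptv.role = "ptv", "ptv"
        structures["ptv"] = ptv
        for name in oar_names:
            prv = expand_margin(structures[name], grid, cfg.prv_margin_mm)
            prv.name, prv.role = name + "_prv", "prv"
            structures[prv.name] = prv
        # normal tissue excludes PTV and OARs
        structures["normal_tissue"] = make_normal_tissue(
            body, [ptv] + [structures[n] for n in oar_names]
        )
        target = "ptv"
        jaw_target = ptv
        oar_suffix = "_prv"

    if cfg.objective_terms is not None:
        terms = [ObjectiveTerm(**t) for t in cfg.objective_terms]
    else:
        from scipy import ndimage

        dist_to_ctv = ndimage.distance_transform_edt(~ctv.mask, sampling=grid.spacing_mm)
        gaps = {
            name: float(dist_to_ctv[structures[name].mask].min()) for name in oar_names
        }
        terms = default_objective_terms(target, gaps, rx, oar_suffix)
    objective = ObjectiveSpec(terms, rx, target)

    fields = make_fields(cfg, grid, jaw_target)
    return PreparedCase(grid, structures, fields, scenarios, objective, target)


def default_metrics(prepared: PreparedCase) -> list[Metric]:
    metrics = [Metric("ctv", "HI_95_107"), Metric("ctv", "Dx", x=2.0), Metric("ctv", "Dx", x=98.0)]
    for name, s in prepared.structures.items():
        if s.role == "oar":
            metrics.append(Metric(name, "Dmean"))
            metrics.append(Metric(name, "Dx", x=2.0))
    metrics.append(Metric("normal_tissue", "V", level_pct=10.0))
    return metrics


def plan_case(cfg: CaseConfig) -> PlanResult:
    """Run the full planning pipeline for one case configuration."""
    prepared = prepare_case(cfg)
    influence = build_dose_influence(
        prepared.fields,
        prepared.grid,
        list(prepared.structures.values()),
        prepared.scenarios,
        normal_tissue_stride=cfg.normal_tissue_stride,
    )
    opt_scenarios = prepared.scenarios if cfg.mode == "robust" else None
    pool, log = run_hybrid_dao(influence, prepared.objective, opt_scenarios, cfg.dao)
    provenance = {"config_hash": cfg.hash(), "seed": cfg.dao.seed, "mode": cfg.mode}
    plan = finalize_plan(
        pool,
        influence,
        prepared.objective,
        opt_scenarios,
        cfg.dao,
        transmission_photon=cfg.transmission_photon,
        transmission_electron=cfg.transmission_electron,
        provenance=provenance,
    )
    if len(plan.apertures) and plan.structure_dose(prepared.target, 0).max() > 0:
        normalize(plan, cfg.prescription.mode, prepared.target, cfg.prescription.level_gy)
    report = robustness_report(
        plan, default_metrics(prepared), cfg.prescription.level_gy, target_structure="ctv"
    )
    return PlanResult(plan, pool, report, log, prepared, cfg)


def evaluate_plan(plan: Plan, prepared: PreparedCase, prescription_gy: float) -> RobustnessReport:
    return robustness_report(plan, default_metrics(prepared), prescription_gy, "ctv")


def compute_dose_grid(plan: Plan, grid: VoxelGrid, scenario: int = 0, chunk: int = 8192) -> VoxelGrid:
    """Total plan dose on the full voxel grid for one scenario.

    Sums, per field, the beamlet doses weighted by the per-beamlet MU
    (open apertures plus MLC transmission through closed leaves), which is
    linear-algebra-identical to summing aperture doses.
    """
    from .finalize import ELECTRON_MLC_TRANSMISSION, PHOTON_MLC_TRANSMISSION

    influence = plan.influence
    shift = influence.scenarios.shifts_mm[scenario]
    n_fields = len(influence.fields)
    beamlet_mu = [np.zeros(f.n_beamlets) for f in influence.fields]
    for a in plan.apertures:
        fld = influence.fields[a.field_index]
        tr = PHOTON_MLC_TRANSMISSION if fld.modality == "photon" else ELECTRON_MLC_TRANSMISSION
        vec = np.full(fld.n_beamlets, tr * a.weight)
        vec[a.open_beamlets(fld.jaw_rect)] = a.weight
        beamlet_mu[a.field_index] += vec

    xs, ys, zs = grid.voxel_centers()
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    total = np.zeros(pts.shape[0])
    for f in range(n_fields):
        if not beamlet_mu[f].any():
            continue
        for i in range(0, pts.shape[0], chunk):
            m = field_dose_matrix(influence.fields[f], grid, shift, pts[i : i + chunk])
            total[i : i + chunk] += m @ beamlet_mu[f]
    return VoxelGrid(grid.shape, grid.spacing_mm, grid.origin_mm, total.reshape(grid.shape))


def write_outputs(result: PlanResult, out_dir) -> dict[str, Path]:
    """Write plan JSON, iteration log CSV, report CSV and summary JSON."""
    import json

    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["case"] = out / "case.h5"
    mio.save_case(paths["case"], result.prepared.grid, list(result.prepared.structures.values()))
    mio.save_scenario_doses(
        paths["case"], result.plan.scenario_dose, result.prepared.scenarios.shifts_mm
    )

    paths["plan"] = out / "plan.json"
    mio.save_plan_record(
        paths["plan"],
        result.plan.apertures,
        result.prepared.fields,
        result.plan.normalization,
        result.plan.provenance,
    )

    paths["log"] = out / "iteration_log.csv"
    pd.DataFrame(result.log).to_csv(paths["log"], index=False)

    paths["report"] = out / "report.csv"
    rep = result.report
    rep.table.to_csv(paths["report"])

    paths["summary"] = out / "summary.json"
    summary = {
        "provenance": result.plan.provenance,
        "normalization": result.plan.normalization,
        "normal_tissue_stride": result.config.normal_tissue_stride,
        "scenario_sd_convention": "population SD over all scenarios incl. nominal",
        "total_mu": rep.total_mu,
        "electron_mu_fraction_pct": rep.electron_mu_fraction_pct,
        "electron_ctv_dmean_fraction_pct": rep.electron_ctv_dmean_fraction_pct,
        "n_apertures": len(result.plan.apertures),
        "final_objective": result.log[-1]["objective"] if result.log else None,
    }
    paths["summary"].write_text(json.dumps(summary, indent=1))
    return paths
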