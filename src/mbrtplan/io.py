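"""HDF5 container and JSON plan records.

Grids, masks and dose arrays live in one HDF5 file per case; the plan
(fields, per-aperture row intervals, MU, normalization, provenance) is a
plain JSON record so it stays human-readable and diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .beams import Field
from .dao import Aperture
from .geometry import Structure, VoxelGrid


def save_case(path, grid: VoxelGrid, structures: list[Structure]) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("grid")
        g.create_dataset("values", data=grid.values, compression="gzip")
        g.attrs["spacing_mm"] = grid.spacing_mm
        g.attrs["origin_mm"] = grid.origin_mm
        sgrp = f.create_group("structures")
        for s in structures:
            ds = sgrp.create_dataset(s.name, data=s.mask.astype(np.uint8), compression="gzip")
            ds.attrs["role"] = s.role


def load_case(path) -> tuple[VoxelGrid, list[Structure]]:
    with h5py.File(path, "r") as f:
        g = f["grid"]
        values = g["values"][()]
        grid = VoxelGrid(
            values.shape, tuple(g.attrs["spacing_mm"]), tuple(g.attrs["origin_mm"]), values
        )
        structures = [
            Structure(name, ds[()].astype(bool), ds.attrs["role"])
            for name, ds in f["structures"].items()
        ]
    return grid, structures


def _field_record(f: Field) -> dict:
    return {
        "id": f.id,
        "modality": f.modality,
        "energy": f.energy,
        "gantry_angle_deg": f.gantry_angle_deg,
        "isocenter_mm": list(f.isocenter_mm),
        "n_rows": f.n_rows,
        "n_cols": f.n_cols,
        "ssd_mm": f.ssd_mm,
        "jaw_rect": list(f.jaw_rect),
    }


def field_from_record(rec: dict) -> Field:
    return Field(
        id=rec["id"],
        modality=rec["modality"],
        energy=rec["energy"],
        gantry_angle_deg=rec["gantry_angle_deg"],
        isocenter_mm=tuple(rec["isocenter_mm"]),
        n_rows=rec["n_rows"],
        n_cols=rec["n_cols"],
        ssd_mm=rec["ssd_mm"],
        jaw_rect=tuple(rec["jaw_rect"]),
    )


def save_plan_record(
    path,
    apertures: list[Aperture],
    fields: list[Field],
    normalization: dict | None,
    provenance: dict,
) -> None:
    rec = {
        "fields": [_field_record(f) for f in fields],
        "apertures": [
            {
                "field_index": a.field_index,
                "field_id": a.field_id,
                "rows": [list(r) if r is not None else None for r in a.rows],
                "mu": a.weight,
            }
            for a in apertures
        ],
        "normalization": normalization,
        "provenance": provenance,
    }
    Path(path).write_text(json.dumps(rec, indent=1))


def load_plan_record(path) -> dict:
    rec = json.loads(Path(path).read_text())
    rec["fields"] = [field_from_record(r) for r in rec["fields"]]
    rec["apertures"] = [
        Aperture(
            a["field_index"],
            a["field_id"],
            [tuple(r) if r is not None else None for r in a["rows"]],
            a["mu"],
        )
        for a in rec["apertures"]
    ]
    return rec


def save_scenario_doses(path, scenario_dose: np.ndarray, shifts_mm: np.ndarray) -> None:
    with h5py.File(path, "a") as f:
        if "plan_dose" in f:
            del f["plan_dose"]
        g = f.create_group("plan_dose")
        g.create_dataset("scenario_dose", data=scenario_dose, compression="gzip")
        g.create_dataset("shifts_mm", data=shifts_mm)
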