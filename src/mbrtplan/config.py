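"""Case configuration: schema, defaults and YAML loading.

A case config fully determines a planning run: the synthetic phantom, the
beam arrangement, the scenario set, the planning mode (robust or
PTV-based), the objective terms, the prescription/normalization and the
DAO knobs.  Every produced artifact embeds the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .dao import DAOConfig
from .geometry import SyntheticCaseSpec


@dataclass
class FieldArrangement:
    """Photon beams at equally spaced gantry angles; electron directions
    with all six clinical energies each, at shortened SSD."""

    n_photon_fields: int = 7
    photon_start_angle_deg: float = 0.0
    electron_gantry_angles_deg: tuple[float, ...] = (-40.0, 0.0, 40.0)
    electron_ssd_mm: tuple[float, ...] = (679.0, 723.0, 823.0)
    electron_energies_mev: tuple[float, ...] = (6.0, 9.0, 12.0, 15.0, 18.0, 22.0)
    jaw_margin_mm: float = 12.0


@dataclass
class PrescriptionConfig:
    mode: str = "D50"  # D50 | D95
    level_gy: float = 60.0


@dataclass
class CaseConfig:
    mode: str = "robust"  # robust | ptv
    case: SyntheticCaseSpec = field(default_factory=SyntheticCaseSpec)
    fields: FieldArrangement = field(default_factory=FieldArrangement)
    scenario_magnitude_mm: float = 5.0
    scenario_axes: tuple[str, ...] = ("LR", "AP", "SI")
    prescription: PrescriptionConfig = field(default_factory=PrescriptionConfig)
    ptv_margin_mm: float = 5.0
    body_crop_mm: float = 3.0
    prv_margin_mm: float = 5.0
    objective_terms: list[dict] | None = None  # None: built-in template
    dao: DAOConfig = field(default_factory=DAOConfig)
    normal_tissue_stride: int = 3
    transmission_photon: float = 0.015
    transmission_electron: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("robust", "ptv"):
            raise ValueError("mode must be 'robust' or 'ptv'")
        if self.mode == "robust" and not self.scenario_axes:
            raise ValueError("robust mode requires at least one scenario axis")
        if self.mode == "ptv" and (self.ptv_margin_mm < 0 or self.body_crop_mm < 0):
            raise ValueError("ptv mode requires non-negative margin parameters")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _dataclass_from_dict(cls, data: dict):
    known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value) if key not in ("objective_terms", "oars") else value
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path_or_dict) -> CaseConfig:
    """Load a CaseConfig from a YAML file path or an equivalent dict."""
    if isinstance(path_or_dict, (str, Path)):
        data = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        data = dict(path_or_dict)
    try:
        if "case" in data:
            data["case"] = _dataclass_from_dict(SyntheticCaseSpec, data["case"])
        if "fields" in data:
            data["fields"] = _dataclass_from_dict(FieldArrangement, data["fields"])
        if "prescription" in data:
            data["prescription"] = _dataclass_from_dict(PrescriptionConfig, data["prescription"])
        if "dao" in data:
            data["dao"] = _dataclass_from_dict(DAOConfig, data["dao"])
        return _dataclass_from_dict(CaseConfig, data)
    except TypeError as exc:
        raise ValueError(f"invalid config: {exc}") from exc
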