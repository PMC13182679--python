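"""File formats: NIfTI masks and dose fields, plan JSON, run configuration.

Masks travel as NIfTI with a diagonal isotropic affine (voxel-center world
coordinates, no shear); plans travel as JSON carrying their grid so shot
positions survive cropping; every output embeds the run seed and a hash of
the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .beam import Plan, Shot
from .env import RewardConfig, TerminationConfig
from .grid import DoseGrid, GridSpec
from .metrics import PlanMetrics
from .ppo import PPOConfig

__all__ = [
    "read_mask",
    "write_mask",
    "write_dose",
    "plan_to_dict",
    "plan_from_dict",
    "write_plan_json",
    "read_plan_json",
    "RunConfig",
    "config_hash",
]

_SPACING_TOL = 1e-4


def _grid_to_affine(grid: GridSpec) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] *= grid.spacing_mm
    affine[:3, 3] = grid.origin_mm
    return affine


def _grid_from_affine(affine: np.ndarray, shape, path) -> GridSpec:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > _SPACING_TOL:
        raise ValueError(f"{path}: sheared/rotated affine is not supported: {rot.tolist()}")
    spacings = np.abs(np.diag(rot))
    if spacings.max() - spacings.min() > _SPACING_TOL:
        raise ValueError(
            f"{path}: anisotropic spacing {spacings.tolist()} mm; isotropic grids required"
        )
    if np.any(np.diag(rot) < 0):
        raise ValueError(f"{path}: negative axis direction in affine not supported")
    return GridSpec(tuple(int(n) for n in shape), float(spacings[0]), tuple(affine[:3, 3]))


def write_mask(path: str | Path, mask: np.ndarray, grid: GridSpec) -> None:
    """Write a binary mask as uint8 NIfTI with the grid's affine."""
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid.shape}")
    data = (np.asarray(mask) != 0).astype(np.uint8)
    nib.save(nib.Nifti1Image(data, _grid_to_affine(grid)), str(path))


def read_mask(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read a NIfTI volume as a binary mask (nonzero -> True) plus its grid."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {img.shape}")
    grid = _grid_from_affine(img.affine, img.shape, path)
    return np.asarray(img.dataobj) != 0, grid


def write_dose(path: str | Path, dose: DoseGrid) -> None:
    nib.save(
        nib.Nifti1Image(dose.values.astype(np.float32), _grid_to_affine(dose.grid)), str(path)
    )


def read_dose(path: str | Path) -> DoseGrid:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape, path)
    return DoseGrid(np.asarray(img.dataobj, dtype=np.float32), grid)


# -- plan JSON -------------------------------------------------------------


def plan_to_dict(
    plan: Plan,
    beam_collimators: tuple[float, ...],
    case_id: str = "",
    metrics: PlanMetrics | None = None,
    seed: int | None = None,
    cfg_hash: str = "",
) -> dict:
    return {
        "case_id": case_id,
        "grid": {
            "shape": list(plan.grid.shape),
            "spacing_mm": plan.grid.spacing_mm,
            "origin_mm": list(plan.grid.origin_mm),
        },
        "prescription_isodose_fraction": plan.prescription_isodose_fraction,
        "shots": [
            {
                "collimator_mm": beam_collimators[s.collimator_index],
                "collimator_index": s.collimator_index,
                "center_ijk": list(s.center),
                "weight": s.weight,
            }
            for s in plan.shots
        ],
        "metrics": dataclasses.asdict(metrics) if metrics is not None else None,
        "seed": seed,
        "config_hash": cfg_hash,
    }


def plan_from_dict(d: dict) -> Plan:
    grid = GridSpec(
        tuple(d["grid"]["shape"]), d["grid"]["spacing_mm"], tuple(d["grid"]["origin_mm"])
    )
    shots = [
        Shot(s["collimator_index"], tuple(s["center_ijk"]), s["weight"]) for s in d["shots"]
    ]
    return Plan(shots, grid, d["prescription_isodose_fraction"])


def write_plan_json(path: str | Path, plan_dict: dict) -> None:
    Path(path).write_text(json.dumps(plan_dict, indent=2) + "\n")


def read_plan_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# -- run configuration -----------------------------------------------------

_SECTION_TYPES = {"reward": RewardConfig, "termination": TerminationConfig, "ppo": PPOConfig}
_TOP_KEYS = {"beam_dir", "seed", "out_dir", "log_level", "iterations",
             "crop_margin_mm", "crop_cap_voxels", "prescription_isodose_fraction",
             "reward", "termination", "ppo"}


@dataclasses.dataclass
class RunConfig:
    """Validated planner configuration (YAML-facing). Unknown keys rejected."""

    reward: RewardConfig = dataclasses.field(default_factory=RewardConfig)
    termination: TerminationConfig = dataclasses.field(default_factory=TerminationConfig)
    ppo: PPOConfig = dataclasses.field(default_factory=PPOConfig)
    beam_dir: str | None = None
    seed: int = 0
    out_dir: str = "."
    log_level: str = "info"
    iterations: int | None = None
    crop_margin_mm: float = 12.0
    crop_cap_voxels: int = 40
    prescription_isodose_fraction: float = 0.5

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for section, typ in _SECTION_TYPES.items():
            if section in raw:
                sub = raw[section]
                valid = {f.name for f in dataclasses.fields(typ)}
                bad = set(sub) - valid
                if bad:
                    raise ValueError(f"unknown keys in {section}: {sorted(bad)}")
                kwargs[section] = typ(**sub)
        for key in _TOP_KEYS - set(_SECTION_TYPES):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(cfg: RunConfig | dict) -> str:
    """Stable short hash of a configuration for output provenance."""
    d = cfg.to_dict() if isinstance(cfg, RunConfig) else cfg
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
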