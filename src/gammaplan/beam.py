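"""TMR-based shot dose engine for a rotating gamma system.

A *shot* is one focused full-arc irradiation at a chosen isocenter with one
of the unit's collimators. Full-arc delivery is modelled as a spherically
symmetric dose kernel: the dose of a shot at voxel ``v`` is

    dose(v) = weight * TMR(depth(center)) * P_c(|v - center| * spacing)

where ``P_c`` is the collimator's radial dose profile (1 on the beam axis,
falling through 0.5 at the collimator's nominal radius) and TMR is the
tissue-maximum ratio at the depth of the shot center inside a spherical
water-equivalent head phantom centered on the grid. Plans are linear
superpositions of weighted shots; plan normalisation (50% isodose) happens
downstream in the metrics chain, so all doses here are relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import DoseGrid, GridSpec

__all__ = [
    "BeamData",
    "Shot",
    "Plan",
    "generate_synthetic_beam_data",
    "load_beam_data",
    "shot_dose",
    "compute_plan_dose",
]

DEFAULT_COLLIMATORS_MM = (4.0, 8.0, 14.0, 18.0)
#: default 80%-20% penumbra width of the synthetic radial profiles, mm
DEFAULT_PENUMBRA_MM = 4.0
#: attenuation coefficient of the synthetic TMR table, 1/mm
TMR_MU_PER_MM = 0.004

_PROFILE_TOL = 1e-6


@dataclass
class BeamData:
    """Per-collimator radial dose profiles plus a TMR table.

    ``radial_profiles[i]`` tabulates the relative off-axis dose of collimator
    ``collimators[i]`` on the common radius grid ``profile_radii_mm``; each
    profile equals 1 on the axis, is non-increasing, and crosses 0.5 near the
    collimator's nominal radius. ``tmr_values`` tabulates the tissue-maximum
    ratio on ``tmr_depths_mm``. Radii beyond the table contribute zero dose.
    """

    collimators: tuple[float, ...]
    profile_radii_mm: np.ndarray
    radial_profiles: np.ndarray  # (n_collimators, n_radii)
    tmr_depths_mm: np.ndarray
    tmr_values: np.ndarray
    phantom_radius_mm: float = 80.0
    _kernel_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.collimators = tuple(float(c) for c in self.collimators)
        self.profile_radii_mm = np.asarray(self.profile_radii_mm, dtype=float)
        self.radial_profiles = np.asarray(self.radial_profiles, dtype=float)
        self.tmr_depths_mm = np.asarray(self.tmr_depths_mm, dtype=float)
        self.tmr_values = np.asarray(self.tmr_values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.collimators) < 1:
            raise ValueError("at least one collimator is required")
        if any(b <= a for a, b in zip(self.collimators, self.collimators[1:])):
            raise ValueError(f"collimator sizes must be strictly increasing: {self.collimators}")
        if self.radial_profiles.shape != (len(self.collimators), self.profile_radii_mm.size):
            raise ValueError("radial_profiles shape does not match collimators x radii")
        if np.any(np.diff(self.profile_radii_mm) <= 0):
            raise ValueError("profile radii must be strictly increasing")
        for i, size in enumerate(self.collimators):
            prof = self.radial_profiles[i]
            if abs(prof[0] - 1.0) > _PROFILE_TOL:
                raise ValueError(f"profile for {size} mm collimator must equal 1 at r=0")
            if np.any(np.diff(prof) > _PROFILE_TOL):
                raise ValueError(f"profile for {size} mm collimator increases with radius")
            if prof.min() >= 0.5:
                raise ValueError(f"profile for {size} mm collimator never falls below 0.5")
        if np.any(self.tmr_values <= 0) or np.any(self.tmr_values > 1.0 + _PROFILE_TOL):
            raise ValueError("TMR values must lie in (0, 1]")
        if self.phantom_radius_mm <= 0:
            raise ValueError("phantom_radius_mm must be positive")

    # -- table lookups ----------------------------------------------------

    def profile(self, collimator_index: int, radius_mm) -> np.ndarray:
        """Relative off-axis dose at ``radius_mm`` (0 beyond the table)."""
        prof = self.radial_profiles[collimator_index]
        return np.interp(radius_mm, self.profile_radii_mm, prof, right=0.0)

    def tmr(self, depth_mm: float) -> float:
        return float(np.interp(depth_mm, self.tmr_depths_mm, self.tmr_values))

    def fifty_percent_radius_mm(self, collimator_index: int) -> float:
        """Radius where the profile crosses 0.5 (the shot's nominal radius)."""
        prof = self.radial_profiles[collimator_index]
        # profiles are non-increasing; interpolate on the reversed table
        return float(np.interp(-0.5, -prof, self.profile_radii_mm))

    def depth_mm(self, center_world: np.ndarray, grid: GridSpec) -> float:
        """Depth of a point inside the spherical head phantom centered on the grid."""
        dist = float(np.linalg.norm(np.asarray(center_world, dtype=float) - grid.center_mm))
        return max(0.0, self.phantom_radius_mm - dist)

    def kernel(self, collimator_index: int, spacing_mm: float) -> np.ndarray:
        """Unit-weight radial kernel sampled on a voxel grid (cached).

        The returned cube has the shot on its center voxel; support is
        truncated at the last profile table radius.
        """
        key = (int(collimator_index), float(spacing_mm))
        cached = self._kernel_cache.get(key)
        if cached is not None:
            return cached
        r_max = float(self.profile_radii_mm[-1])
        half = int(math.floor(r_max / spacing_mm))
        ax = np.arange(-half, half + 1, dtype=float) * spacing_mm
        rr = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2)
        kern = self.profile(collimator_index, rr).astype(np.float32)
        self._kernel_cache[key] = kern
        return kern


@dataclass(frozen=True)
class Shot:
    """One focused irradiation: collimator choice, isocenter voxel, weight."""

    collimator_index: int
    center: tuple[int, int, int]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("shot weight must be non-negative")
        if self.collimator_index < 0:
            raise ValueError("collimator_index must be non-negative")
        object.__setattr__(self, "center", tuple(int(i) for i in self.center))


@dataclass
class Plan:
    """An ordered list of shots on a grid, normalised at a prescription isodose.

    The prescription dose is ``prescription_isodose_fraction`` times the plan's
    maximum dose (default: the 50% isodose line).
    """

    shots: list[Shot] = field(default_factory=list)
    grid: GridSpec = None
    prescription_isodose_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.grid is None:
            raise ValueError("Plan requires a grid")
        if not 0.0 < self.prescription_isodose_fraction < 1.0:
            raise ValueError("prescription_isodose_fraction must be in (0, 1)")

    @property
    def n_shots(self) -> int:
        return len(self.shots)

    def with_weights(self, weights) -> "Plan":
        weights = list(weights)
        if len(weights) != len(self.shots):
            raise ValueError("one weight per shot required")
        shots = [
            Shot(s.collimator_index, s.center, float(w)) for s, w in zip(self.shots, weights)
        ]
        return Plan(shots, self.grid, self.prescription_isodose_fraction)


# -- synthetic beam tables -------------------------------------------------


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_synthetic_beam_data(
    collimator_sizes_mm=DEFAULT_COLLIMATORS_MM,
    penumbra_mm: float = DEFAULT_PENUMBRA_MM,
    out_dir: str | Path | None = None,
    phantom_radius_mm: float = 80.0,
    radius_step_mm: float = 0.25,
    max_radius_mm: float = 25.0,
) -> BeamData:
    """Build a synthetic beam-data fixture (logistic profiles, exponential TMR).

    Stands in for measured commissioning data, which is proprietary. The
    radial profile of a collimator of nominal size ``s`` is a logistic
    ``P(r) = 1 / (1 + exp((r - r0) / a))`` rescaled so that ``P(0) = 1``,
    with ``a = penumbra_mm / (2 ln 4)`` (making ``penumbra_mm`` the 80%-20%
    falloff width) and the shoulder ``r0 = a ln(exp(s/(2a)) - 2)`` chosen in
    closed form so the rescaled profile crosses 0.5 exactly at the nominal
    radius ``s/2``. The TMR table is ``exp(-0.004 d)`` for depths ``d`` in
    [0, 160] mm. When ``out_dir`` is given, writes ``profiles.csv`` and
    ``tmr.csv`` there.
    """
    sizes = tuple(float(s) for s in collimator_sizes_mm)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError(f"collimator sizes must be strictly increasing: {sizes}")
    if penumbra_mm <= 0:
        raise ValueError("penumbra_mm must be positive")

    scale = penumbra_mm / (2.0 * math.log(4.0))
    if math.exp(sizes[0] / (2.0 * scale)) <= 2.0:
        raise ValueError(
            f"penumbra {penumbra_mm} mm is too wide for the {sizes[0]} mm collimator"
        )
    radii = np.arange(0.0, max_radius_mm + radius_step_mm / 2, radius_step_mm)
    profiles = np.empty((len(sizes), radii.size))
    for i, s in enumerate(sizes):
        r0 = scale * math.log(math.exp(s / (2.0 * scale)) - 2.0)
        raw = _logistic((r0 - radii) / scale)
        profiles[i] = raw / raw[0]
    depths = np.arange(0.0, 161.0, 1.0)
    tmr = np.exp(-TMR_MU_PER_MM * depths)

    beam = BeamData(
        collimators=sizes,
        profile_radii_mm=radii,
        radial_profiles=profiles,
        tmr_depths_mm=depths,
        tmr_values=tmr,
        phantom_radius_mm=phantom_radius_mm,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prof_df = pd.DataFrame({"radius_mm": radii})
        for i, s in enumerate(sizes):
            prof_df[f"{s:g}"] = profiles[i]
        prof_df.to_csv(out_dir / "profiles.csv", index=False)
        pd.DataFrame({"depth_mm": depths, "tmr": tmr}).to_csv(out_dir / "tmr.csv", index=False)
    return beam


def packaged_beam_data() -> BeamData:
    """The beam-data fixture shipped with the package (synthetic tables)."""
    from importlib import resources

    with resources.as_file(resources.files("gammaplan.data") / "beam") as p:
        return load_beam_data(p)


def load_beam_data(path: str | Path, phantom_radius_mm: float = 80.0) -> BeamData:
    """Load and validate beam data from ``profiles.csv`` + ``tmr.csv`` in a directory.

    Violated invariants (non-monotone profile, axis value != 1, non-positive
    TMR) are rejected, not repaired.
    """
    path = Path(path)
    prof_path, tmr_path = path / "profiles.csv", path / "tmr.csv"
    for p in (prof_path, tmr_path):
        if not p.exists():
            raise FileNotFoundError(f"missing beam data table: {p}")
    prof_df = pd.read_csv(prof_path)
    tmr_df = pd.read_csv(tmr_path)
    if "radius_mm" not in prof_df.columns:
        raise ValueError("profiles.csv must have a radius_mm column")
    if not {"depth_mm", "tmr"} <= set(tmr_df.columns):
        raise ValueError("tmr.csv must have depth_mm and tmr columns")
    coll_cols = [c for c in prof_df.columns if c != "radius_mm"]
    try:
        sizes = tuple(float(c) for c in coll_cols)
    except ValueError as exc:
        raise ValueError(f"profile columns must be collimator sizes in mm: {coll_cols}") from exc
    return BeamData(
        collimators=sizes,
        profile_radii_mm=prof_df["radius_mm"].to_numpy(),
        radial_profiles=prof_df[coll_cols].to_numpy().T,
        tmr_depths_mm=tmr_df["depth_mm"].to_numpy(),
        tmr_values=tmr_df["tmr"].to_numpy(),
        phantom_radius_mm=phantom_radius_mm,
    )


# -- dose superposition ----------------------------------------------------


def _add_shot_dose(
    out: np.ndarray, beam: BeamData, shot: Shot, grid: GridSpec, amplitude: float
) -> None:
    """Accumulate ``amplitude * kernel`` centered on the shot, clipped to the grid."""
    kern = beam.kernel(shot.collimator_index, grid.spacing_mm)
    half = kern.shape[0] // 2
    src = []
    dst = []
    for axis in range(3):
        c, n = shot.center[axis], grid.shape[axis]
        lo, hi = c - half, c + half + 1
        src.append(slice(max(0, -lo), kern.shape[axis] - max(0, hi - n)))
        dst.append(slice(max(0, lo), min(n, hi)))
    out[tuple(dst)] += amplitude * kern[tuple(src)]


def shot_amplitude(beam: BeamData, shot: Shot, grid: GridSpec) -> float:
    """Dose at the shot's own center voxel: weight x TMR at the center's depth."""
    depth = beam.depth_mm(grid.index_to_world(shot.center), grid)
    return shot.weight * beam.tmr(depth)


def shot_dose(beam: BeamData, shot: Shot, grid: GridSpec) -> DoseGrid:
    """Dose field of a single shot on ``grid``."""
    if not grid.contains_index(shot.center):
        raise ValueError(f"shot center {shot.center} outside grid {grid.shape}")
    if shot.collimator_index >= len(beam.collimators):
        raise ValueError(f"collimator_index {shot.collimator_index} out of range")
    out = np.zeros(grid.shape, dtype=np.float32)
    _add_shot_dose(out, beam, shot, grid, shot_amplitude(beam, shot, grid))
    return DoseGrid(out, grid)


def compute_plan_dose(plan: Plan, beam: BeamData, grid: GridSpec | None = None) -> DoseGrid:
    """Pointwise superposition of all shot doses (empty plan -> zero field)."""
    grid = grid or plan.grid
    out = np.zeros(grid.shape, dtype=np.float32)
    for shot in plan.shots:
        if not grid.contains_index(shot.center):
            raise ValueError(f"shot center {shot.center} outside grid {grid.shape}")
        _add_shot_dose(out, beam, shot, grid, shot_amplitude(beam, shot, grid))
    return DoseGrid(out, grid)
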