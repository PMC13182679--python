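"""Sequential shot-placement environment.

One episode builds one plan: the agent repeatedly places a weighted shot
inside the still-uncovered part of the target, the dose field and the 50%
isodose prescription level are recomputed, and the agent is rewarded for
gains in coverage and selectivity minus a penalty on dose spilled outside
the target. The observation is four binary mask channels:

* state0  feasibility mask — target voxels not yet inside the prescription
          isodose region (the only legal shot positions),
* state1  the prescription (50%) isodose region of the current dose,
* state2  the union of organ-at-risk masks (carried as context only),
* state3  overdose mask — prescription isodose region outside the target.

The episode ends when the coverage/selectivity criteria are met, when the
target is fully covered (no feasible action remains), or at a shot cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beam import BeamData, Plan, Shot, shot_amplitude, _add_shot_dose
from .grid import DoseGrid, GridSpec
from .metrics import PlanMetrics, conformity_indices
from .phantoms import Case

__all__ = [
    "PlanningState",
    "Action",
    "RewardConfig",
    "TerminationConfig",
    "StepResult",
    "build_state",
    "reward_fn",
    "PlanningEnv",
]


@dataclass(frozen=True)
class PlanningState:
    """The four binary mask channels observed by the agent."""

    state0: np.ndarray  # feasibility: target \ isodose
    state1: np.ndarray  # prescription isodose region
    state2: np.ndarray  # OAR union
    state3: np.ndarray  # overdose: isodose \ target

    def stack(self) -> np.ndarray:
        """Channels-first float32 tensor for the networks."""
        return np.stack(
            [self.state0, self.state1, self.state2, self.state3]
        ).astype(np.float32)

    def check_identities(self, ptv: np.ndarray) -> None:
        """Assert the defining set-algebra identities against the target."""
        ptv = np.asarray(ptv, dtype=bool)
        if np.any(self.state0 & self.state1):
            raise AssertionError("state0 and state1 overlap")
        if not np.array_equal(self.state0 | (self.state1 & ptv), ptv):
            raise AssertionError("state0 union covered-target does not equal the target")
        if not np.array_equal(self.state3, self.state1 & ~ptv):
            raise AssertionError("state3 is not the isodose region outside the target")


@dataclass(frozen=True)
class Action:
    """A shot choice: collimator, voxel position, discrete weight level."""

    collimator_index: int
    position: tuple[int, int, int]
    weight_level: int = 0


@dataclass(frozen=True)
class RewardConfig:
    """Weights of the per-step reward
    ``w_cov * dCov + w_si * dSI - w_spill * spill``.

    ``spill`` is the current spill fraction; relative to the prescription
    isodose volume (``1 - SI``) by default, or to the target volume when
    ``spill_base="tv"``.
    """

    w_cov: float = 1.0
    w_si: float = 1.0
    w_spill: float = 0.5
    spill_base: str = "piv"

    def __post_init__(self) -> None:
        if min(self.w_cov, self.w_si, self.w_spill) < 0:
            raise ValueError("reward weights must be non-negative")
        if self.spill_base not in ("piv", "tv"):
            raise ValueError("spill_base must be 'piv' or 'tv'")


@dataclass(frozen=True)
class TerminationConfig:
    """Episode stop criteria: clinical thresholds and a shot cap."""

    cov_min: float = 0.95
    si_min: float = 0.80
    max_shots: int = 30

    def __post_init__(self) -> None:
        if not (0.0 < self.cov_min <= 1.0 and 0.0 < self.si_min <= 1.0):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.max_shots < 1:
            raise ValueError("max_shots must be >= 1")

    def satisfied(self, metrics: PlanMetrics) -> bool:
        return metrics.coverage >= self.cov_min and metrics.selectivity >= self.si_min


@dataclass(frozen=True)
class StepResult:
    next_state: PlanningState
    reward: float
    done: bool
    metrics: PlanMetrics


def build_state(ptv: np.ndarray, oars: np.ndarray, dose: np.ndarray, rx: float) -> PlanningState:
    """Assemble the four-channel state from target, OARs, dose and rx level."""
    ptv = np.asarray(ptv, dtype=bool)
    oars = np.asarray(oars, dtype=bool)
    if ptv.shape != dose.shape or oars.shape != dose.shape:
        raise ValueError("ptv/oars/dose shapes differ")
    isodose = dose >= rx if rx > 0 else np.zeros_like(ptv)
    return PlanningState(
        state0=ptv & ~isodose,
        state1=isodose,
        state2=oars,
        state3=isodose & ~ptv,
    )


def reward_fn(prev: PlanMetrics, new: PlanMetrics, cfg: RewardConfig) -> float:
    """Weighted coverage/selectivity gains minus the current spill penalty."""
    if cfg.spill_base == "piv":
        spill = (1.0 - new.selectivity) if new.piv_cc > 0 else 0.0
    else:
        spill = (new.piv_cc - new.tv_piv_cc) / new.tv_cc
    return (
        cfg.w_cov * (new.coverage - prev.coverage)
        + cfg.w_si * (new.selectivity - prev.selectivity)
        - cfg.w_spill * spill
    )


class PlanningEnv:
    """Stateful episode driver for one case.

    Keeps the raw (unnormalised) dose field, the per-shot dose contributions,
    and the running plan; recomputes the prescription level after every shot
    so the prescription always rides the 50% isodose of the evolving plan.
    """

    def __init__(
        self,
        case: Case,
        beam: BeamData,
        reward_cfg: RewardConfig | None = None,
        term_cfg: TerminationConfig | None = None,
        prescription_isodose_fraction: float = 0.5,
        weight_levels: tuple[float, ...] = (1.0,),
    ):
        if not np.any(case.target):
            raise ValueError("case target is empty")
        self.case = case
        self.beam = beam
        self.grid: GridSpec = case.grid
        self.reward_cfg = reward_cfg or RewardConfig()
        self.term_cfg = term_cfg or TerminationConfig()
        self.rx_fraction = prescription_isodose_fraction
        self.weight_levels = tuple(float(w) for w in weight_levels)
        self._ptv = np.asarray(case.target, dtype=bool)
        self._n_ptv = int(np.count_nonzero(self._ptv))
        self._oars = np.zeros(self.grid.shape, dtype=bool)
        for mask in case.oars.values():
            self._oars |= np.asarray(mask, dtype=bool)
        self.reset()

    # -- episode lifecycle ------------------------------------------------

    def reset(self) -> PlanningState:
        self.dose = np.zeros(self.grid.shape, dtype=np.float32)
        self.shot_doses: list[np.ndarray] = []
        self.shots: list[Shot] = []
        self.rx = 0.0
        self.done = False
        self.metrics = self._empty_metrics()
        self.state = build_state(self._ptv, self._oars, self.dose, self.rx)
        return self.state

    def _empty_metrics(self) -> PlanMetrics:
        tv_cc = self._n_ptv * self.grid.voxel_volume_cc
        return PlanMetrics(tv_cc, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0)

    @property
    def plan(self) -> Plan:
        return Plan(list(self.shots), self.grid, self.rx_fraction)

    def executable_mask(self, collimator_index: int | None = None) -> np.ndarray:
        """Legal shot positions: the uncovered-target (state0) voxels.

        The feasible region is the same for every collimator; the argument
        is accepted for interface symmetry with per-collimator policies.
        """
        return self.state.state0

    def _compute_metrics(self) -> PlanMetrics:
        n_piv = int(np.count_nonzero(self.state.state1))
        n_both = n_piv - int(np.count_nonzero(self.state.state3))
        vox = self.grid.voxel_volume_cc
        cov = n_both / self._n_ptv
        si = n_both / n_piv if n_piv else 0.0
        if si > 0:
            ci_rtog, ci_paddick = conformity_indices(cov, si)
        else:
            ci_rtog = ci_paddick = 0.0
        return PlanMetrics(
            self._n_ptv * vox, n_piv * vox, n_both * vox,
            cov, si, ci_rtog, ci_paddick, self.rx, len(self.shots),
        )

    def step(self, action: Action) -> StepResult:
        """Place one shot, rebuild state/metrics, return the reward and flag."""
        if self.done:
            raise RuntimeError("episode already terminated")
        if not self.state.state0[tuple(action.position)]:
            raise ValueError(f"position {action.position} is not executable")
        if not 0 <= action.collimator_index < len(self.beam.collimators):
            raise ValueError("collimator_index out of range")
        weight = self.weight_levels[action.weight_level]
        shot = Shot(action.collimator_index, tuple(action.position), weight)

        contrib = np.zeros(self.grid.shape, dtype=np.float32)
        _add_shot_dose(contrib, self.beam, shot, self.grid, shot_amplitude(self.beam, shot, self.grid))
        self.shots.append(shot)
        self.shot_doses.append(contrib)
        self.dose += contrib
        self.rx = self.rx_fraction * float(self.dose.max())

        prev_metrics = self.metrics
        self.state = build_state(self._ptv, self._oars, self.dose, self.rx)
        self.metrics = self._compute_metrics()
        reward = reward_fn(prev_metrics, self.metrics, self.reward_cfg)
        self.done = (
            self.term_cfg.satisfied(self.metrics)
            or len(self.shots) >= self.term_cfg.max_shots
            or not self.state.state0.any()
        )
        return StepResult(self.state, reward, self.done, self.metrics)

    def dose_grid(self) -> DoseGrid:
        return DoseGrid(self.dose.copy(), self.grid)
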