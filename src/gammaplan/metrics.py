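"""Plan-quality indices for radiosurgery plans.

Definitions (TV = target volume, PIV = prescription isodose volume,
TV_PIV = their intersection):

* coverage          Cov = TV_PIV / TV
* selectivity       SI  = TV_PIV / PIV
* CI (RTOG)         PIV / TV  = Cov / SI
* CI (Paddick)      TV_PIV^2 / (TV * PIV) = Cov * SI
* spill fraction    (PIV - TV_PIV) / PIV = 1 - SI

The prescription dose is a fixed fraction of the plan's maximum dose
(50% isodose by default), so every index is invariant under global
rescaling of shot weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .beam import BeamData, Plan, compute_plan_dose
from .grid import DoseGrid

__all__ = [
    "PlanMetrics",
    "DVHCurve",
    "round_half_away",
    "prescription_level",
    "coverage_selectivity",
    "conformity_indices",
    "spill_fraction",
    "dvh",
    "evaluate_plan",
    "compare_cohorts",
]


def round_half_away(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero at ``decimals`` places.

    Uses exact decimal arithmetic on the shortest repr of ``value`` so that
    quantities that are exact ties in decimal (e.g. 0.98 / 0.80 = 1.225)
    round the way they are printed in clinical tables, not the way their
    nearest binary float happens to fall.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PlanMetrics:
    """Summary indices of one evaluated plan."""

    tv_cc: float
    piv_cc: float
    tv_piv_cc: float
    coverage: float
    selectivity: float
    ci_rtog: float
    ci_paddick: float
    rx_dose: float
    n_shots: int = 0

    def rounded(self, decimals: int = 2) -> "PlanMetrics":
        """Copy with indices rounded half-away-from-zero for reporting."""
        return PlanMetrics(
            tv_cc=self.tv_cc,
            piv_cc=self.piv_cc,
            tv_piv_cc=self.tv_piv_cc,
            coverage=round_half_away(self.coverage, decimals),
            selectivity=round_half_away(self.selectivity, decimals),
            ci_rtog=round_half_away(self.ci_rtog, decimals),
            ci_paddick=round_half_away(self.ci_paddick, decimals),
            rx_dose=self.rx_dose,
            n_shots=self.n_shots,
        )


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram: fraction of a structure at >= dose."""

    dose_bins: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose_bins", np.asarray(self.dose_bins, dtype=float))
        object.__setattr__(self, "volume_fraction", np.asarray(self.volume_fraction, dtype=float))
        if self.dose_bins.shape != self.volume_fraction.shape:
            raise ValueError("dose_bins and volume_fraction must have the same length")


def prescription_level(dose: DoseGrid, fraction: float = 0.5) -> float:
    """Prescription dose = ``fraction`` x maximum dose (the isodose line)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    dmax = dose.max
    if dmax <= 0:
        raise ValueError("dose field is all zero; prescription level undefined")
    return fraction * dmax


def _check_same_grid(dose: DoseGrid, mask: np.ndarray) -> None:
    if mask.shape != dose.values.shape:
        raise ValueError(f"mask shape {mask.shape} does not match dose {dose.values.shape}")


def coverage_selectivity(
    dose: DoseGrid, target_mask: np.ndarray, rx: float
) -> tuple[float, float, float, float, float]:
    """Coverage, selectivity and the three volumes (cc) behind them.

    Returns ``(coverage, selectivity, tv_cc, piv_cc, tv_piv_cc)``. With an
    empty prescription isodose volume, selectivity is defined as 0.
    """
    _check_same_grid(dose, target_mask)
    target = np.asarray(target_mask, dtype=bool)
    n_tv = int(np.count_nonzero(target))
    if n_tv == 0:
        raise ValueError("target mask is empty")
    piv = dose.values >= rx
    n_piv = int(np.count_nonzero(piv))
    n_both = int(np.count_nonzero(piv & target))
    vox = dose.grid.voxel_volume_cc
    coverage = n_both / n_tv
    selectivity = n_both / n_piv if n_piv else 0.0
    return coverage, selectivity, n_tv * vox, n_piv * vox, n_both * vox


def conformity_indices(
    coverage: float, selectivity: float, decimals: int | None = None
) -> tuple[float, float]:
    """RTOG and Paddick conformity indices from coverage and selectivity.

    ``ci_rtog = coverage / selectivity`` (identically PIV/TV) and
    ``ci_paddick = coverage * selectivity``. With ``decimals`` set, both are
    computed in exact decimal arithmetic from the inputs' printed values and
    rounded half-away-from-zero — the convention used to reproduce published
    plan-quality tables.
    """
    if selectivity <= 0:
        if coverage > 0:
            raise ValueError("selectivity 0 with nonzero coverage is inconsistent")
        raise ValueError("conformity indices undefined for selectivity 0")
    if decimals is not None:
        cov_d, si_d = Decimal(repr(float(coverage))), Decimal(repr(float(selectivity)))
        q = Decimal(1).scaleb(-decimals)
        ci_rtog = float((cov_d / si_d).quantize(q, rounding=ROUND_HALF_UP))
        ci_paddick = float((cov_d * si_d).quantize(q, rounding=ROUND_HALF_UP))
        return ci_rtog, ci_paddick
    return coverage / selectivity, coverage * selectivity


def spill_fraction(dose: DoseGrid, target_mask: np.ndarray, rx: float) -> float:
    """Fraction of the prescription isodose volume lying outside the target."""
    _check_same_grid(dose, target_mask)
    target = np.asarray(target_mask, dtype=bool)
    piv = dose.values >= rx
    n_piv = int(np.count_nonzero(piv))
    if n_piv == 0:
        return 0.0
    n_out = int(np.count_nonzero(piv & ~target))
    return n_out / n_piv


def dvh(dose: DoseGrid, mask: np.ndarray, n_bins: int = 100) -> DVHCurve:
    """Cumulative DVH of ``mask``: fraction receiving at least each dose level.

    Bin 0 sits at dose 0 (fraction 1 by definition); the last bin sits at
    the structure's maximum dose.
    """
    _check_same_grid(dose, mask)
    mask = np.asarray(mask, dtype=bool)
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("mask is empty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    vals = dose.values[mask]
    levels = np.linspace(0.0, float(vals.max()), n_bins + 1)
    frac = np.array([np.count_nonzero(vals >= lv) / n for lv in levels])
    frac[0] = 1.0
    return DVHCurve(levels, frac)


def evaluate_plan(
    plan: Plan,
    beam: BeamData,
    target_mask: np.ndarray,
    oar_masks: dict[str, np.ndarray] | None = None,
    n_bins: int = 100,
    dose: DoseGrid | None = None,
) -> tuple[PlanMetrics, dict[str, DVHCurve]]:
    """Compute dose, prescription level and all indices for a plan.

    A precomputed ``dose`` may be passed to avoid re-superposing shots.
    Returns the metrics and DVH curves for the target plus any OARs.
    An empty plan (zero dose) yields coverage 0 and undefined (0) indices.
    """
    if dose is None:
        dose = compute_plan_dose(plan, beam)
    target = np.asarray(target_mask, dtype=bool)
    tv_cc = dose.grid.volume_cc(target)
    if dose.max <= 0:
        metrics = PlanMetrics(tv_cc, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, plan.n_shots)
        return metrics, {}
    rx = prescription_level(dose, plan.prescription_isodose_fraction)
    cov, si, tv_cc, piv_cc, tv_piv_cc = coverage_selectivity(dose, target, rx)
    if si > 0:
        ci_rtog, ci_paddick = conformity_indices(cov, si)
    else:
        ci_rtog = ci_paddick = 0.0
    metrics = PlanMetrics(tv_cc, piv_cc, tv_piv_cc, cov, si, ci_rtog, ci_paddick, rx, plan.n_shots)
    curves = {"target": dvh(dose, target, n_bins)}
    for name, m in (oar_masks or {}).items():
        if np.any(m):
            curves[name] = dvh(dose, np.asarray(m, dtype=bool), n_bins)
    return metrics, curves


_INDEX_FIELDS = ("coverage", "selectivity", "ci_rtog", "ci_paddick")


def compare_cohorts(
    metrics_a: list[PlanMetrics], metrics_b: list[PlanMetrics]
) -> dict[str, dict[str, float | bool]]:
    """Paired two-sided t-tests on per-case index differences between cohorts.

    Cases must be paired by position. For each index returns the t statistic,
    the p-value, the mean difference (a - b), and a ``degenerate`` flag for
    zero-variance difference vectors; an all-zero difference vector reports
    p = 1.0 by convention.
    """
    if len(metrics_a) != len(metrics_b):
        raise ValueError("cohorts must be paired: lengths differ")
    if len(metrics_a) < 2:
        raise ValueError("need at least two paired cases")
    out: dict[str, dict[str, float | bool]] = {}
    for name in _INDEX_FIELDS:
        a = np.array([getattr(m, name) for m in metrics_a], dtype=float)
        b = np.array([getattr(m, name) for m in metrics_b], dtype=float)
        diff = a - b
        if np.allclose(diff.std(ddof=1), 0.0):
            # zero-variance differences: t undefined
            p = 1.0 if np.allclose(diff, 0.0) else 0.0
            out[name] = {
                "statistic": float("nan"),
                "pvalue": p,
                "mean_diff": float(diff.mean()),
                "degenerate": True,
            }
            continue
        res = stats.ttest_rel(a, b)
        out[name] = {
            "statistic": float(res.statistic),
            "pvalue": float(res.pvalue),
            "mean_diff": float(diff.mean()),
            "degenerate": False,
        }
    return out
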