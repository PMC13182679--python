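"""Plan-quality indices: coverage/selectivity/conformity, DVH, cohort tests."""

import numpy as np
import pytest

from gammaplan.beam import Plan, Shot
from gammaplan.grid import DoseGrid, GridSpec
from gammaplan.metrics import (
    PlanMetrics,
    compare_cohorts,
    conformity_indices,
    coverage_selectivity,
    dvh,
    evaluate_plan,
    prescription_level,
    spill_fraction,
)
from gammaplan.phantoms import load_table2


def _random_field(rng, n=16):
    grid = GridSpec((n, n, n))
    dose = DoseGrid(rng.random((n, n, n)).astype(np.float32), grid)
    mask = rng.random((n, n, n)) < 0.3
    mask[n // 2, n // 2, n // 2] = True  # never empty
    return dose, mask


class TestPrescriptionLevel:
    def test_half_of_max(self, small_grid):
        vals = np.zeros(small_grid.shape, np.float32)
        vals[10, 10, 10] = 40.0
        assert prescription_level(DoseGrid(vals, small_grid), 0.5) == 20.0

    def test_homogeneous_in_dose_scale(self, rng):
        dose, _ = _random_field(rng)
        scaled = DoseGrid(3.0 * dose.values, dose.grid)
        assert prescription_level(scaled, 0.5) == pytest.approx(
            3.0 * prescription_level(dose, 0.5), rel=1e-6
        )

    def test_threshold_count_matches_brute_force(self, rng):
        dose, _ = _random_field(rng)
        rx = prescription_level(dose, 0.5)
        fast = int(np.count_nonzero(dose.values >= rx))
        brute = sum(
            1
            for i in range(16)
            for j in range(16)
            for k in range(16)
            if dose.values[i, j, k] >= rx
        )
        assert fast == brute

    def test_zero_field_rejected(self, small_grid):
        with pytest.raises(ValueError):
            prescription_level(DoseGrid.zeros(small_grid), 0.5)


class TestCoverageSelectivity:
    def test_perfect_conformity(self, small_grid):
        mask = np.zeros(small_grid.shape, bool)
        mask[8:13, 8:13, 8:13] = True
        dose = DoseGrid(np.where(mask, 2.0, 0.5).astype(np.float32), small_grid)
        cov, si, tv, piv, tvpiv = coverage_selectivity(dose, mask, rx=1.0)
        assert (cov, si) == (1.0, 1.0)
        assert tv == piv == tvpiv

    def test_zero_dose_has_zero_coverage(self, small_grid):
        mask = np.zeros(small_grid.shape, bool)
        mask[10, 10, 10] = True
        cov, si, *_ = coverage_selectivity(DoseGrid.zeros(small_grid), mask, rx=1.0)
        assert cov == 0.0 and si == 0.0

    def test_matches_brute_force_voxel_counts(self, rng):
        dose, mask = _random_field(rng)
        rx = 0.6
        cov, si, tv, piv, tvpiv = coverage_selectivity(dose, mask, rx)
        n_tv = n_piv = n_both = 0
        for idx in np.ndindex(dose.values.shape):
            t, p = mask[idx], dose.values[idx] >= rx
            n_tv += t
            n_piv += p
            n_both += t and p
        assert cov == pytest.approx(n_both / n_tv)
        assert si == pytest.approx(n_both / n_piv)
        vox = dose.grid.voxel_volume_cc
        assert (tv, piv, tvpiv) == pytest.approx((n_tv * vox, n_piv * vox, n_both * vox))

    def test_empty_target_rejected(self, small_grid, rng):
        dose, _ = _random_field(rng, 21)
        with pytest.raises(ValueError, match="empty"):
            coverage_selectivity(dose, np.zeros(small_grid.shape, bool), 0.5)


class TestConformityIndices:
    @pytest.mark.parametrize(
        "cov,si,exp_rtog,exp_paddick",
        [
            (0.96, 0.76, 1.26, 0.73),  # validation case 1026002, auto plan
            (0.94, 0.87, 1.08, 0.82),  # validation case 1026011, auto plan
            (0.98, 0.80, 1.23, 0.78),  # decimal tie 1.225 rounds away from zero
        ],
    )
    def test_published_worked_examples(self, cov, si, exp_rtog, exp_paddick):
        assert conformity_indices(cov, si, decimals=2) == (exp_rtog, exp_paddick)

    def test_equal_cov_and_si_give_rtog_one(self):
        ci_rtog, ci_paddick = conformity_indices(0.85, 0.85)
        assert ci_rtog == pytest.approx(1.0)
        assert ci_paddick == pytest.approx(0.85**2)

    def test_product_identity(self, rng):
        for _ in range(50):
            cov, si = rng.uniform(0.05, 1.0, 2)
            ci_rtog, ci_paddick = conformity_indices(cov, si)
            assert ci_rtog * ci_paddick == pytest.approx(cov**2, abs=1e-9)
            assert ci_rtog >= ci_paddick

    def test_zero_selectivity_rejected(self):
        with pytest.raises(ValueError):
            conformity_indices(0.5, 0.0)

    def test_all_published_rows_reproduce(self):
        """Every printed CI pair follows from its printed (Cov, SI)."""
        fixture = load_table2()
        for _, row in fixture.records.iterrows():
            for arm in ("manual", "auto"):
                got = conformity_indices(
                    row[f"coverage_pct_{arm}"] / 100.0, row[f"si_{arm}"], decimals=2
                )
                assert got == (row[f"ci_rtog_{arm}"], row[f"ci_paddick_{arm}"]), row["id"]


class TestSpillFraction:
    def test_perfect_conformity_spills_nothing(self, small_grid):
        mask = np.zeros(small_grid.shape, bool)
        mask[8:13, 8:13, 8:13] = True
        dose = DoseGrid(np.where(mask, 2.0, 0.0).astype(np.float32), small_grid)
        assert spill_fraction(dose, mask, 1.0) == 0.0

    def test_complement_of_selectivity(self, rng):
        dose, mask = _random_field(rng)
        _, si, *_ = coverage_selectivity(dose, mask, 0.6)
        assert spill_fraction(dose, mask, 0.6) == pytest.approx(1.0 - si)

    def test_zero_piv_spills_nothing(self, small_grid):
        mask = np.zeros(small_grid.shape, bool)
        mask[10, 10, 10] = True
        assert spill_fraction(DoseGrid.zeros(small_grid), mask, 1.0) == 0.0


class TestDVH:
    def test_uniform_dose_is_a_step(self, small_grid):
        mask = np.zeros(small_grid.shape, bool)
        mask[5:10, 5:10, 5:10] = True
        dose = DoseGrid(np.where(mask, 4.0, 0.0).astype(np.float32), small_grid)
        curve = dvh(dose, mask, n_bins=8)
        assert curve.volume_fraction[0] == 1.0
        assert np.all(curve.volume_fraction[curve.dose_bins <= 4.0] == 1.0)

    def test_curve_non_increasing(self, rng):
        dose, mask = _random_field(rng)
        curve = dvh(dose, mask, n_bins=40)
        assert np.all(np.diff(curve.volume_fraction) <= 0)

    def test_fraction_at_rx_equals_coverage(self, beam, sphere_case):
        plan = Plan([Shot(2, tuple(s // 2 for s in sphere_case.grid.shape), 1.0)],
                    sphere_case.grid)
        metrics, curves = evaluate_plan(plan, beam, sphere_case.target, n_bins=400)
        frac_at_rx = float(
            np.interp(metrics.rx_dose - 1e-9, curves["target"].dose_bins,
                      curves["target"].volume_fraction)
        )
        assert frac_at_rx == pytest.approx(metrics.coverage, abs=0.01)

    def test_empty_mask_rejected(self, small_grid):
        with pytest.raises(ValueError):
            dvh(DoseGrid.zeros(small_grid), np.zeros(small_grid.shape, bool))


class TestEvaluatePlan:
    def test_empty_plan_has_zero_coverage(self, beam, sphere_case):
        metrics, _ = evaluate_plan(Plan([], sphere_case.grid), beam, sphere_case.target)
        assert metrics.coverage == 0.0

    def test_large_collimator_covers_small_sphere(self, beam, sphere_case):
        """A 14 mm shot (7 mm half-radius) covers a ~6 mm-radius sphere."""
        center = tuple(s // 2 for s in sphere_case.grid.shape)
        plan = Plan([Shot(2, center, 1.0)], sphere_case.grid)
        metrics, _ = evaluate_plan(plan, beam, sphere_case.target)
        assert metrics.coverage >= 0.99

    def test_metrics_invariant_under_weight_scaling(self, beam, sphere_case):
        center = tuple(s // 2 for s in sphere_case.grid.shape)
        shots = [Shot(1, center, 1.0), Shot(0, (center[0] + 3,) + center[1:], 0.5)]
        m1, _ = evaluate_plan(Plan(shots, sphere_case.grid), beam, sphere_case.target)
        scaled = [Shot(s.collimator_index, s.center, 10 * s.weight) for s in shots]
        m2, _ = evaluate_plan(Plan(scaled, sphere_case.grid), beam, sphere_case.target)
        assert m1.coverage == m2.coverage
        assert m1.selectivity == m2.selectivity
        assert m1.ci_paddick == pytest.approx(m2.ci_paddick, abs=1e-12)


def _metrics_list(values):
    return [
        PlanMetrics(1, 1, 1, v, v, 1.0, v * v, 1.0) for v in values
    ]


class TestCompareCohorts:
    def test_identical_cohorts_report_p_one(self):
        a = _metrics_list([0.9, 0.95, 0.85])
        out = compare_cohorts(a, _metrics_list([0.9, 0.95, 0.85]))
        assert out["coverage"]["pvalue"] == 1.0
        assert out["coverage"]["degenerate"]

    def test_constant_nonzero_difference_flagged(self):
        out = compare_cohorts(_metrics_list([1.0, 2.0, 3.0]), _metrics_list([0.0, 1.0, 2.0]))
        assert out["coverage"]["degenerate"]
        assert out["coverage"]["mean_diff"] == pytest.approx(1.0)

    def test_matches_sign_flip_permutation_oracle(self, rng):
        a = _metrics_list(rng.normal(0.9, 0.05, size=30))
        b = _metrics_list(rng.normal(0.88, 0.05, size=30))
        out = compare_cohorts(a, b)
        diff = np.array([x.coverage for x in a]) - np.array([x.coverage for x in b])
        signs = rng.choice([-1.0, 1.0], size=(100_000, diff.size))
        perm_means = (signs * diff).mean(axis=1)
        p_perm = float(np.mean(np.abs(perm_means) >= abs(diff.mean())))
        assert out["coverage"]["pvalue"] == pytest.approx(p_perm, abs=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_cohorts(_metrics_list([1, 2]), _metrics_list([1, 2, 3]))
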