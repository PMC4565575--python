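"""Cumulative coverage, CVH and robustness analysis."""

import copy

import numpy as np
import pytest

from ectplan.coverage import (
    compute_coverage,
    coverage_fraction,
    coverage_progression,
    cumulative_field,
    cvh,
    robustness_sweep,
)
from ectplan.fixtures import toy_slab_fixture
from ectplan.phantom import TissueProperties
from ectplan.solver import SolverConfig, solve_schedule
from ectplan.electrodes import rasterize


class TestCumulativeField:
    def test_single_pair_is_identity(self, toy_case):
        sols = toy_case["solutions"]
        assert np.array_equal(cumulative_field(sols[:1]), sols[0].field_magnitude)

    def test_duplicated_pair_is_idempotent(self, toy_case):
        sols = toy_case["solutions"]
        once = cumulative_field(sols[:1])
        twice = cumulative_field([sols[0], sols[0]])
        assert np.array_equal(once, twice)

    def test_dominates_every_pair(self, toy_case):
        sols = toy_case["solutions"]
        cum = cumulative_field(sols)
        for s in sols:
            assert np.all(cum >= s.field_magnitude)

    def test_mismatched_grids_rejected(self, toy_case):
        sols = toy_case["solutions"]
        other = copy.copy(sols[0])
        other.field_magnitude = other.field_magnitude[:-1]
        with pytest.raises(ValueError, match="grid"):
            cumulative_field([sols[0], other])


class TestCoverageFraction:
    def test_threshold_zero_is_full_coverage(self):
        field = np.random.default_rng(0).uniform(0, 500, (5, 5, 5))
        mask = np.ones_like(field, dtype=bool)
        assert coverage_fraction(field, mask, 0.0) == 1.0

    def test_threshold_above_max_is_zero(self):
        field = np.full((4, 4, 4), 300.0)
        mask = np.ones_like(field, dtype=bool)
        assert coverage_fraction(field, mask, 1e6) == 0.0

    def test_half_and_half_construction(self):
        field = np.zeros((2, 5, 1))
        field[0] = 500.0
        field[1] = 300.0
        mask = np.ones_like(field, dtype=bool)
        assert coverage_fraction(field, mask, 400.0) == 0.5

    def test_threshold_is_inclusive(self):
        field = np.full((3, 3, 3), 400.0)
        mask = np.ones_like(field, dtype=bool)
        assert coverage_fraction(field, mask, 400.0) == 1.0

    def test_empty_mask_rejected(self):
        field = np.zeros((3, 3, 3))
        with pytest.raises(ValueError, match="empty"):
            coverage_fraction(field, np.zeros_like(field, dtype=bool), 100.0)


class TestCVH:
    def test_matches_coverage_fraction_pointwise(self, toy_case):
        field = cumulative_field(toy_case["solutions"])
        mask = toy_case["phantom"].tumor_mask
        thresholds = [0.0, 200.0, 400.0, 800.0, 1600.0]
        table = cvh(field, mask, thresholds)
        for t, frac in table:
            assert frac == coverage_fraction(field, mask, t)

    def test_nonincreasing_and_endpoints(self, toy_case):
        field = cumulative_field(toy_case["solutions"])
        mask = toy_case["phantom"].tumor_mask
        fracs = [f for _, f in cvh(field, mask, np.linspace(0, 2000, 21))]
        assert fracs[0] == 1.0
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_uniform_field_steps_at_its_value(self):
        field = np.full((4, 4, 4), 450.0)
        mask = np.ones_like(field, dtype=bool)
        table = dict(cvh(field, mask, [0.0, 450.0, 450.1]))
        assert table[0.0] == 1.0
        assert table[450.0] == 1.0  # inclusive threshold
        assert table[450.1] == 0.0

    def test_unsorted_thresholds_rejected(self):
        field = np.zeros((3, 3, 3))
        mask = np.ones_like(field, dtype=bool)
        with pytest.raises(ValueError, match="sorted"):
            cvh(field, mask, [400.0, 100.0])

    def test_invariant_under_pair_permutation(self, toy_case, tissue_table):
        # max is commutative: reversing the delivery order leaves the CVH
        sols = toy_case["solutions"]
        mask = toy_case["phantom"].tumor_mask
        thresholds = np.linspace(0, 1500, 16)
        forward = cvh(cumulative_field(sols), mask, thresholds)
        backward = cvh(cumulative_field(sols[::-1]), mask, thresholds)
        assert forward == backward


class TestProgression:
    def test_prefix_coverage_nondecreasing(self, toy_case):
        sols = toy_case["solutions"] * 2
        mask = toy_case["phantom"].tumor_mask
        prog = coverage_progression(sols, mask, 400.0)
        assert all(a <= b for a, b in zip(prog, prog[1:]))
        assert prog[-1] == coverage_fraction(cumulative_field(sols), mask, 400.0)


class TestComputeCoverage:
    def test_report_fields_consistent(self, toy_case, tissue_table):
        report = compute_coverage(
            toy_case["solutions"], toy_case["phantom"], tissue_table, margin_width=4.0
        )
        assert 0.0 <= report.tumor_coverage_at(400.0) <= 1.0
        assert report.per_pair[0]["pair"] == [1, 2]
        d = report.to_dict()
        assert d["cvh"][0]["fraction"] == 1.0


class TestVoltageMonotonicity:
    def test_scaling_voltages_up_never_lowers_coverage(self, tissue_table):
        # electroporation disabled: field scales linearly with voltage
        phantom, array, schedule = toy_slab_fixture(spacing=2.0)
        masks = rasterize(array, phantom, min_radius=1.5)
        cfg = SolverConfig(electroporation=False)
        base = solve_schedule(phantom, tissue_table, array, schedule, cfg,
                              electrode_masks=masks)
        boosted_schedule = schedule.with_voltages(
            {e.voltage: e.voltage * 1.1 for e in schedule}
        )
        boosted = solve_schedule(phantom, tissue_table, array, boosted_schedule, cfg,
                                 electrode_masks=masks)
        mask = phantom.tumor_mask
        for thr in np.linspace(50, 1500, 12):
            assert coverage_fraction(cumulative_field(boosted), mask, thr) >= \
                coverage_fraction(cumulative_field(base), mask, thr)


class TestRobustness:
    def test_empty_ensemble_equals_nominal(self, toy_case, tissue_table):
        summary = robustness_sweep(
            toy_case["phantom"], tissue_table, toy_case["array"], toy_case["schedule"],
            SolverConfig(), n_members=0, seed=1, rasterize_min_radius=1.5,
        )
        assert summary.min == summary.mean == summary.max == summary.nominal

    def test_nominal_within_ensemble_range(self, toy_case, tissue_table):
        summary = robustness_sweep(
            toy_case["phantom"], tissue_table, toy_case["array"], toy_case["schedule"],
            SolverConfig(), shift_radius_mm=1.0, sigma_scale=0.2, n_members=4, seed=11,
            rasterize_min_radius=1.5,
        )
        pool = summary.members + [summary.nominal]
        assert summary.min == pytest.approx(min(pool))
        assert summary.max == pytest.approx(max(pool))
        assert summary.min <= summary.nominal <= summary.max

    def test_members_match_brute_force_recomputation(self, toy_case, tissue_table):
        """Each ensemble member equals an explicit re-solve of the shifted,
        rescaled plan generated with the same seed."""
        phantom, array, schedule = (
            toy_case["phantom"], toy_case["array"], toy_case["schedule"]
        )
        seed, n = 23, 3
        summary = robustness_sweep(
            phantom, tissue_table, array, schedule, SolverConfig(),
            shift_radius_mm=1.0, sigma_scale=0.2, n_members=n, seed=seed,
            rasterize_min_radius=1.5,
        )
        # regenerate the same perturbations and recompute from scratch
        from ectplan.coverage import _uniform_in_sphere

        rng = np.random.default_rng(seed)
        expected = []
        for _ in range(n):
            shift = _uniform_in_sphere(rng, 1.0)
            scale = rng.uniform(0.8, 1.2)
            table = {
                code: TissueProperties(p.sigma0 * scale, p.sigma_factor, p.e_rev,
                                       p.e_irrev)
                for code, p in tissue_table.items()
            }
            arr = array.translated(shift)
            masks = rasterize(arr, phantom, min_radius=1.5)
            sols = solve_schedule(phantom, table, arr, schedule, SolverConfig(),
                                  electrode_masks=masks)
            expected.append(
                coverage_fraction(cumulative_field(sols), phantom.tumor_mask,
                                  tissue_table[1].e_rev)
            )
        assert summary.members == pytest.approx(expected)

    def test_negative_perturbation_rejected(self, toy_case, tissue_table):
        with pytest.raises(ValueError):
            robustness_sweep(
                toy_case["phantom"], tissue_table, toy_case["array"],
                toy_case["schedule"], SolverConfig(), shift_radius_mm=-1.0,
            )
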