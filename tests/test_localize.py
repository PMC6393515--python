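"""Dipole grid scans, confidence intervals, verdicts, contingency rates."""

import numpy as np
import pytest

from deepmeg.forward import (
    Sphere,
    compute_leadfield,
    make_grid,
    make_helmet,
    tangential_unit,
)
from deepmeg.localize import (
    ContingencyStats,
    SphericalAtlas,
    contingency_stats,
    double_dipole_scan,
    evaluate_localization,
    single_dipole_scan,
)


def _topo_from_grid_point(leadfield, gi, sphere, amplitude=1.0):
    ori = tangential_unit(leadfield.grid[gi], sphere)
    return amplitude * (ori @ leadfield.gain[gi])


class TestSingleDipoleScan:
    def test_exact_recovery(self, leadfield_coarse, sphere):
        gi = len(leadfield_coarse.grid) // 3
        topo = _topo_from_grid_point(leadfield_coarse, gi, sphere)
        gof_map = single_dipole_scan(topo, leadfield_coarse)
        assert gof_map.argmax == gi
        assert gof_map.max_gof == pytest.approx(1.0, abs=1e-10)
        assert gof_map.valid
        # every CI member explains essentially all variance
        assert np.all(gof_map.gof[gof_map.ci_indices] >= 1.0 - 1e-9)

    def test_ci_threshold_algebra(self, leadfield_coarse, sphere):
        gi = 10
        rng = np.random.default_rng(0)
        topo = _topo_from_grid_point(leadfield_coarse, gi, sphere)
        noisy = topo + 0.35 * np.sqrt(np.mean(topo**2)) * rng.standard_normal(len(topo))
        gof_map = single_dipole_scan(noisy, leadfield_coarse)
        expected = gof_map.max_gof - (1.0 - gof_map.max_gof)
        assert gof_map.ci_threshold == pytest.approx(expected)
        assert gof_map.argmax in gof_map.ci_indices

    def test_gof_scale_invariance(self, leadfield_coarse, sphere):
        rng = np.random.default_rng(1)
        topo = _topo_from_grid_point(leadfield_coarse, 5, sphere)
        topo = topo + 0.1 * np.sqrt(np.mean(topo**2)) * rng.standard_normal(len(topo))
        m1 = single_dipole_scan(topo, leadfield_coarse)
        m2 = single_dipole_scan(topo * 7.3, leadfield_coarse)
        np.testing.assert_allclose(m1.gof, m2.gof, atol=1e-12)

    def test_gof_bounded(self, leadfield_coarse):
        rng = np.random.default_rng(2)
        gof_map = single_dipole_scan(
            rng.standard_normal(leadfield_coarse.gain.shape[2]), leadfield_coarse
        )
        assert np.all(gof_map.gof >= 0.0) and np.all(gof_map.gof <= 1.0)

    def test_noise_topography_inconclusive(self, leadfield_coarse):
        rng = np.random.default_rng(3)
        n_inconclusive = 0
        for _ in range(20):
            topo = rng.standard_normal(leadfield_coarse.gain.shape[2])
            if not single_dipole_scan(topo, leadfield_coarse).valid:
                n_inconclusive += 1
        assert n_inconclusive >= 19

    def test_noise_ci_coverage(self, leadfield_coarse, sphere):
        rng = np.random.default_rng(4)
        covered = total = 0
        for _ in range(40):
            gi = int(rng.integers(len(leadfield_coarse.grid)))
            topo = _topo_from_grid_point(leadfield_coarse, gi, sphere)
            noisy = topo + 0.10 * np.sqrt(np.mean(topo**2)) * rng.standard_normal(
                len(topo)
            )
            gof_map = single_dipole_scan(noisy, leadfield_coarse)
            if gof_map.valid:
                total += 1
                covered += gi in gof_map.ci_indices
        assert total > 30
        assert covered / total >= 0.95


@pytest.fixture(scope="module")
def tiny_leadfield():
    sphere = Sphere()
    sensors = make_helmet(n_sensors=48)
    grid = make_grid(sphere, spacing=0.025)
    return compute_leadfield(grid, sensors, sphere, spacing=0.025), sphere


class TestDoubleDipoleScan:
    def test_two_source_recovery(self, tiny_leadfield):
        leadfield, sphere = tiny_leadfield
        gi, gj = 4, len(leadfield.grid) - 5
        topo = _topo_from_grid_point(leadfield, gi, sphere) + _topo_from_grid_point(
            leadfield, gj, sphere
        )
        result = double_dipole_scan(topo, leadfield)
        assert result.valid
        assert result.max_gof == pytest.approx(1.0, abs=1e-9)
        retained_pairs = result.pairs[result.retained]
        assert any(set(p) == {gi, gj} for p in retained_pairs)
        # score-map maximum on one of the true points
        assert result.best_point in (gi, gj)

    def test_pair_gof_dominates_single(self, tiny_leadfield):
        leadfield, sphere = tiny_leadfield
        rng = np.random.default_rng(0)
        topo = _topo_from_grid_point(leadfield, 7, sphere)
        topo += 0.3 * np.sqrt(np.mean(topo**2)) * rng.standard_normal(len(topo))
        result = double_dipole_scan(topo, leadfield)
        single_gof = result.single_map.gof
        best_member = np.maximum(
            single_gof[result.pairs[:, 0]], single_gof[result.pairs[:, 1]]
        )
        assert np.all(result.pair_gof >= best_member - 1e-9)

    def test_single_source_not_split(self, tiny_leadfield):
        # with one true generator the pair scan must not fabricate a
        # distant second source: retained pairs (if any) contain the point
        leadfield, sphere = tiny_leadfield
        rng = np.random.default_rng(1)
        gi = 11
        topo = _topo_from_grid_point(leadfield, gi, sphere)
        topo += 0.05 * np.sqrt(np.mean(topo**2)) * rng.standard_normal(len(topo))
        result = double_dipole_scan(topo, leadfield)
        if result.retained.any():
            true_pos = leadfield.grid[gi]
            for pi, pj in result.pairs[result.retained]:
                dmin = min(
                    np.linalg.norm(leadfield.grid[pi] - true_pos),
                    np.linalg.norm(leadfield.grid[pj] - true_pos),
                )
                assert dmin <= 2.0 * leadfield.spacing

    def test_sensor_count_guard(self, sphere):
        sensors = make_helmet(n_sensors=6)
        grid = make_grid(sphere, spacing=0.03)
        lf = compute_leadfield(grid, sensors, sphere, spacing=0.03)
        with pytest.raises(ValueError, match="7"):
            double_dipole_scan(np.ones(6), lf)


class TestEvaluateLocalization:
    def test_region_classes(self, leadfield_coarse, sphere):
        atlas = SphericalAtlas()
        deep = [i for i, p in enumerate(leadfield_coarse.grid)
                if np.linalg.norm(p) < 0.035]
        gi = deep[0]
        topo = _topo_from_grid_point(leadfield_coarse, gi, sphere)
        verdict = evaluate_localization(
            single_dipole_scan(topo, leadfield_coarse),
            atlas,
            leadfield_coarse.grid[gi],
        )
        assert verdict.region_class == "mesial"
        assert verdict.structure_in_ci

    def test_invalid_map_is_inconclusive(self, leadfield_coarse):
        rng = np.random.default_rng(5)
        topo = rng.standard_normal(leadfield_coarse.gain.shape[2])
        gof_map = single_dipole_scan(topo, leadfield_coarse)
        assert not gof_map.valid
        verdict = evaluate_localization(gof_map, SphericalAtlas(), None)
        assert verdict.region_class == "inconclusive"
        assert not verdict.structure_in_ci

    def test_position_outside_hull_warns(self, leadfield_coarse, sphere):
        topo = _topo_from_grid_point(leadfield_coarse, 3, sphere)
        gof_map = single_dipole_scan(topo, leadfield_coarse)
        with pytest.warns(UserWarning, match="hull"):
            verdict = evaluate_localization(
                gof_map, SphericalAtlas(), np.array([1.0, 1.0, 1.0])
            )
        assert not verdict.structure_in_ci


class TestContingencyStats:
    def test_printed_cohort_rates(self):
        stats = ContingencyStats(
            mesial_mesial=27,
            mesial_lateral=2,
            lateral_mesial=6,
            lateral_lateral=28,
            mesial_in_ci=21,
            lateral_in_ci=21,
        )
        display = stats.display()
        assert display["sensitivity"] == "0.81"
        assert display["specificity"] == "0.93"
        assert display["region_sensitivity_mesial"] == "0.77"
        assert display["region_sensitivity_lateral"] == "0.75"

    def test_all_correct(self):
        stats = ContingencyStats(10, 0, 0, 10, 10, 10)
        assert stats.sensitivity == 1.0
        assert stats.specificity == 1.0

    @pytest.mark.parametrize(
        "mm, ml, lm, ll, sens, spec",
        [(5, 0, 0, 5, 1.0, 1.0), (4, 1, 1, 4, 0.8, 0.8)],
    )
    def test_small_tables(self, mm, ml, lm, ll, sens, spec):
        stats = ContingencyStats(mm, ml, lm, ll, mm, ll)
        assert stats.sensitivity == pytest.approx(sens)
        assert stats.specificity == pytest.approx(spec)

    def test_from_records_with_inconclusive(self):
        records = (
            [{"truth_class": "mesial", "localized_class": "mesial", "structure_in_ci": True}] * 3
            + [{"truth_class": "mesial", "localized_class": "inconclusive", "structure_in_ci": False}] * 2
            + [{"truth_class": "lateral", "localized_class": "lateral", "structure_in_ci": False}] * 4
        )
        stats = contingency_stats(records)
        assert stats.mesial_mesial == 3
        assert stats.lateral_lateral == 4
        assert stats.n_inconclusive == 2
        assert stats.sensitivity == 1.0

    def test_empty_column_reported_missing(self):
        stats = ContingencyStats(0, 0, 0, 5, 0, 3)
        assert stats.sensitivity is None
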