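"""Weighted KDE, highest-density isopleths, and the bandwidth sweep."""

import math

import numpy as np
import pytest

from mpaud.ud_estimation import (
    GridSpec,
    is_contiguous,
    select_bandwidth,
    ud_contour,
    weighted_kde,
)


from oracles import brute_force_density, oracle_sweep


def small_spec(width=20_000.0, height=16_000.0, cell=200.0):
    return GridSpec(x0=-width / 2, y0=-height / 2, width=width, height=height, cell_m=cell)


class TestWeightedKDE:
    def test_matches_brute_force_oracle(self):
        """Separable-evaluation KDE equals the direct Gaussian double sum."""
        spec = small_spec()
        for seed in range(5):
            r = np.random.default_rng(seed)
            pts = r.uniform(-6000, 6000, size=(50, 2))
            w = r.uniform(0.1, 1.0, 50)
            h = r.uniform(400, 2000)
            grid = weighted_kde(pts, w, spec, h)
            oracle = brute_force_density(pts, w, spec, h)
            cells = r.integers(0, [spec.ny, spec.nx], size=(20, 2))
            for iy, ix in cells:
                assert grid.density[iy, ix] == pytest.approx(oracle[iy, ix], rel=1e-10)

    def test_single_point_mode_and_mass(self):
        spec = small_spec()
        grid = weighted_kde(np.array([[500.0, -300.0]]), np.array([1.0]), spec, 800.0)
        iy, ix = np.unravel_index(np.argmax(grid.density), grid.density.shape)
        assert abs(spec.x_centers()[ix] - 500.0) <= spec.cell_m
        assert abs(spec.y_centers()[iy] + 300.0) <= spec.cell_m
        assert grid.density.sum() * spec.cell_area == pytest.approx(1.0, abs=1e-6)

    def test_zero_weight_point_excluded(self):
        spec = small_spec()
        g1 = weighted_kde(np.array([[0.0, 0.0], [5000.0, 5000.0]]),
                          np.array([1.0, 0.0]), spec, 600.0)
        g2 = weighted_kde(np.array([[0.0, 0.0]]), np.array([1.0]), spec, 600.0)
        np.testing.assert_allclose(g1.density, g2.density, atol=1e-15)

    def test_all_points_outside_extent_is_error(self):
        spec = small_spec()
        with pytest.raises(ValueError, match="outside"):
            weighted_kde(np.array([[1e6, 1e6]]), np.array([1.0]), spec, 500.0)

    def test_negative_weights_rejected(self):
        spec = small_spec()
        with pytest.raises(ValueError, match="non-negative"):
            weighted_kde(np.zeros((2, 2)), np.array([1.0, -0.5]), spec, 500.0)


class TestUDContour:
    def test_single_fix_hdr_area_matches_gaussian_closed_form(self):
        """area(p) = -2 pi h^2 ln(1-p) for one Gaussian kernel; p=0.5 gives 2 pi h^2 ln 2."""
        spec = GridSpec(x0=-33_700 / 2, y0=-19_300 / 2, cell_m=100.0)
        h = 1000.0
        grid = weighted_kde(np.array([[0.0, 0.0]]), np.array([1.0]), spec, h)
        c50 = ud_contour(grid, 0.5)
        assert c50.area_m2 == pytest.approx(2 * math.pi * h**2 * math.log(2), rel=0.03)

    def test_nesting_and_area_monotonicity(self, rng):
        spec = small_spec()
        pts = rng.normal(scale=1500.0, size=(80, 2))
        grid = weighted_kde(pts, np.ones(80), spec, 700.0)
        c50, c90 = ud_contour(grid, 0.5), ud_contour(grid, 0.9)
        assert c50.area_m2 < c90.area_m2
        assert np.all(c90.mask[c50.mask])  # 50% cells are a subset of 90% cells

    def test_mass_accounting_bounds(self, rng):
        spec = small_spec()
        pts = rng.normal(scale=2000.0, size=(60, 2))
        grid = weighted_kde(pts, rng.uniform(0.2, 1, 60), spec, 900.0)
        for p in (0.3, 0.5, 0.9):
            c = ud_contour(grid, p)
            mass = grid.cell_mass()[c.mask].sum()
            assert p <= mass < p + grid.cell_mass().max() + 1e-12

    def test_two_distant_point_masses_give_two_components(self):
        spec = small_spec()
        pts = np.array([[-6000.0, 0.0], [6000.0, 0.0]])
        grid = weighted_kde(pts, np.ones(2), spec, 500.0)
        c50 = ud_contour(grid, 0.5)
        assert c50.n_components == 2
        assert not is_contiguous(c50)

    def test_degenerate_level_rejected(self, rng):
        spec = small_spec()
        grid = weighted_kde(rng.normal(size=(5, 2)) * 1000, np.ones(5), spec, 500.0)
        with pytest.raises(ValueError):
            ud_contour(grid, 1.5)

    def test_polygon_area_matches_cell_count(self, rng):
        spec = small_spec()
        pts = rng.normal(scale=1500.0, size=(40, 2))
        grid = weighted_kde(pts, np.ones(40), spec, 800.0)
        c = ud_contour(grid, 0.5)
        assert c.polygons.area == pytest.approx(c.area_m2, rel=1e-9)

    def test_halving_cell_size_changes_single_fix_area_below_one_percent(self):
        h = 1000.0
        areas = []
        for cell in (200.0, 100.0):
            spec = GridSpec(x0=-33_700 / 2, y0=-19_300 / 2, cell_m=cell)
            grid = weighted_kde(np.array([[0.0, 0.0]]), np.array([1.0]), spec, h)
            areas.append(ud_contour(grid, 0.5).area_m2)
        assert abs(areas[1] - areas[0]) / areas[0] < 0.01


class TestContiguity:
    def test_unimodal_sample_contiguous(self, rng):
        spec = small_spec()
        pts = rng.normal(scale=1200.0, size=(100, 2))
        grid = weighted_kde(pts, np.ones(100), spec, 900.0)
        assert is_contiguous(ud_contour(grid, 0.5))

    def test_two_clusters_small_bandwidth_fragmented(self, rng):
        spec = small_spec(width=30_000)
        pts = np.vstack([rng.normal(scale=300, size=(30, 2)) + [-5000, 0],
                         rng.normal(scale=300, size=(30, 2)) + [5000, 0]])
        grid = weighted_kde(pts, np.ones(60), spec, 500.0)
        assert not is_contiguous(ud_contour(grid, 0.5))

    def test_oversmoothing_merges_modes(self, rng):
        spec = small_spec(width=30_000)
        pts = np.vstack([rng.normal(scale=300, size=(30, 2)) + [-5000, 0],
                         rng.normal(scale=300, size=(30, 2)) + [5000, 0]])
        grid = weighted_kde(pts, np.ones(60), spec, 8000.0)
        assert is_contiguous(ud_contour(grid, 0.5))


class TestSelectBandwidth:
    def test_matches_exhaustive_oracle_on_two_cluster_family(self):
        spec = small_spec(width=30_000, height=20_000, cell=250.0)
        for seed, sep in enumerate([4000, 6000, 9000]):
            r = np.random.default_rng(seed)
            pts = np.vstack([r.normal(scale=400, size=(25, 2)) + [-sep / 2, 0],
                             r.normal(scale=400, size=(25, 2)) + [sep / 2, 0]])
            w = r.uniform(0.5, 1.0, 50)
            sel = select_bandwidth(pts, w, spec, h_start=5000.0, h_min=250.0)
            expect_h, expect_rule = oracle_sweep(pts, w, spec, 5000.0, 250.0)
            assert sel.chosen_h == pytest.approx(expect_h)
            assert sel.rule == expect_rule

    def test_decrement_is_250_m(self, rng):
        spec = small_spec()
        pts = rng.normal(scale=1000, size=(40, 2))
        sel = select_bandwidth(pts, np.ones(40), spec, h_start=3000.0, h_min=250.0)
        diffs = np.diff(sel.candidates)
        assert np.allclose(diffs, -250.0)

    def test_single_tight_cluster_reaches_floor(self, rng):
        spec = small_spec()
        pts = rng.uniform(-50, 50, size=(30, 2))
        sel = select_bandwidth(pts, np.ones(30), spec, h_start=2000.0, h_min=250.0)
        assert sel.floor_reached
        assert sel.rule == "two_polygon_fallback"

    def test_h_start_below_floor_is_error(self, rng):
        spec = small_spec()
        with pytest.raises(ValueError, match="h_start"):
            select_bandwidth(rng.normal(size=(10, 2)), np.ones(10), spec,
                             h_start=250.0, h_min=250.0)
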