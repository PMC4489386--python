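"""Brownian bridge UD, sig1 estimation and isopleth extraction."""

import numpy as np
import pytest
from scipy.integrate import quad

from bearlink.bbmm import (
    BridgeParams,
    TruncationError,
    UDGrid,
    backward_ellipses,
    bridge_density,
    bridge_density_at,
    bridge_sigma2,
    estimate_sig1,
    isopleth_polygon,
)
from bearlink.synthetic import simulate_bridge_track
from bearlink.telemetry import segment_trajectory

from .conftest import fix_at


PARAMS = BridgeParams(sig1=300.0, sig2=5.0)


class TestBridgeDensity:
    def test_mass_conserved_on_default_grid(self):
        ud = bridge_density(fix_at(0, 0, 0), fix_at(2, 400, 150), PARAMS, cell=10)
        assert 1 - 1e-3 <= ud.total_mass() <= 1 + 1e-9

    def test_same_point_ud_is_rotation_symmetric(self):
        # stationary animal: UD must be invariant under 90-degree rotation
        a, b = fix_at(0, 0, 0), fix_at(2, 0, 0)
        ud = bridge_density(a, b, BridgeParams(sig1=100, sig2=5), cell=10)
        v = ud.values
        # grid is symmetric about the fix by construction
        assert np.allclose(v, np.rot90(v), rtol=1e-9, atol=1e-15)

    def test_degenerate_bridge_hugs_the_segment(self):
        # sig1, sig2 -> 0: the UD collapses onto the straight segment; the
        # needle is thinner than a cell, so the captured mass (not ~1 under
        # cell-centre quadrature) must sit within one cell of the segment
        p = BridgeParams(sig1=1e-3, sig2=1e-3)
        a, b = fix_at(0, 0, 0), fix_at(2, 200, 0)
        ud = bridge_density(a, b, p, cell=10, check_truncation=False)
        xc, yc = np.meshgrid(ud.x_centers(), ud.y_centers())
        # distance from the segment y=0, 0<=x<=200
        dx = np.clip(np.where(xc < 0, -xc, np.where(xc > 200, xc - 200, 0)), 0, None)
        d = np.hypot(dx, yc)
        near = d <= 10.0
        assert ud.values[near].sum() >= 0.99 * ud.total_mass()

    def test_density_matches_adaptive_quadrature(self):
        # integrand check: dense midpoint rule against scipy adaptive quad
        # (probes away from the fixes, where the time integrand develops a
        # boundary layer that only matters exactly at the endpoints)
        a, b = fix_at(0, 0, 0), fix_at(2, 400, 150)
        probes = np.array(
            [[200, 75], [150, -50], [350, 250], [100, 100], [300, 0]]
        )
        dense = bridge_density_at(probes, a, b, PARAMS, time_steps=50000)

        T = 2.0
        def integrand(t, px, py):
            al = t / T
            s2 = bridge_sigma2(t, T, PARAMS.sig1, PARAMS.sig2)
            mx, my = a.x + al * (b.x - a.x), a.y + al * (b.y - a.y)
            return np.exp(-((px - mx) ** 2 + (py - my) ** 2) / (2 * s2)) / (
                2 * np.pi * s2 * T
            )

        for (px, py), d in zip(probes, dense):
            oracle, _ = quad(integrand, 0, T, args=(px, py), epsrel=1e-10, limit=200)
            assert d == pytest.approx(oracle, rel=1e-6)

    def test_default_quadrature_error_is_small(self):
        a, b = fix_at(0, 0, 0), fix_at(2, 400, 150)
        probes = np.array([[200.0, 75.0], [100.0, 0.0]])
        coarse = bridge_density_at(probes, a, b, PARAMS, time_steps=100)
        dense = bridge_density_at(probes, a, b, PARAMS, time_steps=50000)
        assert np.allclose(coarse, dense, rtol=1e-3)

    def test_translation_equivariance(self):
        a, b = fix_at(0, 0, 0), fix_at(2, 400, 150)
        ud0 = bridge_density(a, b, PARAMS, cell=10)
        shift = 5000.0  # multiple of the cell size keeps the lattice aligned
        a2, b2 = fix_at(0, shift, shift), fix_at(2, 400 + shift, 150 + shift)
        ud1 = bridge_density(a2, b2, PARAMS, cell=10)
        assert ud0.values.shape == ud1.values.shape
        assert np.allclose(ud0.values, ud1.values, atol=1e-12)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            bridge_density(fix_at(0, 0, 0), fix_at(0, 1, 1), PARAMS)

    def test_undersized_grid_raises_truncation_error(self):
        a, b = fix_at(0, 0, 0), fix_at(2, 400, 150)
        with pytest.raises(TruncationError, match="enlarge"):
            bridge_density(a, b, PARAMS, cell=10, grid_origin=(0, 0),
                           grid_shape=(10, 10))


class TestEstimateSig1:
    def test_straight_line_track_hits_lower_bound(self):
        fixes = [fix_at(2 * i, 400.0 * i, 0.0) for i in range(9)]
        traj = segment_trajectory(fixes)
        est = estimate_sig1(traj, sig2=0.0, search_interval=(0.5, 100.0))
        assert est.at_boundary
        assert est.value == pytest.approx(0.5, rel=0.05)

    def test_parameter_recovery_from_bridge_simulation(self):
        rng = np.random.default_rng(123)
        traj = simulate_bridge_track(500, sig1=5.0, sig2=5.0, rng=rng)
        est = estimate_sig1(traj, sig2=5.0, search_interval=(0.5, 100.0))
        assert 4.5 <= est.value <= 5.5
        assert not est.at_boundary

    def test_median_error_over_replicates(self):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            traj = simulate_bridge_track(500, sig1=5.0, sig2=5.0, rng=rng)
            est = estimate_sig1(traj, sig2=5.0, search_interval=(0.5, 100.0))
            errs.append(abs(est.value - 5.0))
        assert np.median(errs) < 0.5

    def test_too_few_triples(self):
        traj = segment_trajectory([fix_at(0, 0, 0), fix_at(2, 10, 0), fix_at(4, 0, 0)])
        with pytest.raises(ValueError, match="triples"):
            estimate_sig1(traj, sig2=5.0)


def _gaussian_ud(sigma: float, cell: float = 4.0, half: float = None) -> UDGrid:
    half = half or 6 * sigma
    n = int(2 * half / cell)
    c = cell * (np.arange(n) + 0.5) - half
    gx = np.exp(-(c**2) / (2 * sigma**2))
    v = np.outer(gx, gx)
    v = v / v.sum()
    return UDGrid(origin=(-half, -half), cell_size=(cell, cell), values=v)


class TestIsopleth:
    def test_single_cell_ud(self):
        v = np.zeros((5, 5))
        v[2, 2] = 1.0
        ud = UDGrid(origin=(0, 0), cell_size=(10, 10), values=v)
        iso = isopleth_polygon(ud, 0.75)
        assert iso.attained_mass == pytest.approx(1.0)
        assert iso.geometry.area == pytest.approx(100.0)
        assert iso.geometry.bounds == (20.0, 20.0, 30.0, 30.0)

    def test_circular_gaussian_closed_form_area(self):
        # 75% region of a circular normal has area -2*pi*sigma^2*ln(0.25)
        sigma = 30.0
        iso = isopleth_polygon(_gaussian_ud(sigma, cell=2.0), 0.75)
        expected = -2 * np.pi * sigma**2 * np.log(0.25)
        assert iso.area == pytest.approx(expected, rel=0.05)

    def test_area_monotone_in_level(self):
        ud = _gaussian_ud(30.0, cell=4.0)
        areas = [isopleth_polygon(ud, lv).area for lv in (0.25, 0.5, 0.75, 0.95)]
        assert all(a < b for a, b in zip(areas, areas[1:]))

    def test_area_increases_with_sig1(self):
        a, b = fix_at(0, 0, 0), fix_at(2, 300, 0)
        areas = []
        for s1 in (100.0, 200.0, 400.0):
            ud = bridge_density(a, b, BridgeParams(sig1=s1, sig2=5.0), cell=10)
            areas.append(isopleth_polygon(ud, 0.75).area)
        assert areas[0] < areas[1] < areas[2]

    def test_degenerate_ud_rejected(self):
        ud = UDGrid(origin=(0, 0), cell_size=(10, 10), values=np.zeros((4, 4)))
        with pytest.raises(ValueError):
            isopleth_polygon(ud)


class TestBackwardEllipses:
    def _track(self, n=16, gap_at=None):
        fixes = []
        for i in range(n):
            if gap_at is not None and i == gap_at:
                continue
            fixes.append(fix_at(2 * i, 400.0 * i, 0.0))
        return segment_trajectory(fixes)

    def test_transit_window_selects_four_steps(self):
        traj = self._track()
        be = backward_ellipses(traj, 15, (10, 16), PARAMS, cell=20)
        assert sorted(be.step_end_lags_h) == [10.0, 12.0, 14.0, 16.0]

    def test_full_day_window_gives_twelve_steps(self):
        traj = self._track()
        be = backward_ellipses(traj, 15, (0, 24), PARAMS, cell=20)
        assert len(be.polygons) == 12

    def test_flagged_gap_removes_one_bridge(self):
        traj = self._track(gap_at=9)  # missing fix creates a 4-h step
        be = backward_ellipses(traj, 14, (0, 24), PARAMS, cell=20)
        full = backward_ellipses(self._track(), 15, (0, 24), PARAMS, cell=20)
        assert be.skipped_gaps == 1
        assert len(be.polygons) < len(full.polygons)

    def test_empty_window_warns(self):
        traj = self._track(n=3)
        with pytest.warns(UserWarning, match="no eligible"):
            be = backward_ellipses(traj, 2, (10, 16), PARAMS, cell=20)
        assert be.polygons == []
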