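"""Filament geometry: resampling, mode decomposition, curvature, bending energy, I/O."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import actent as ae
import actent.geometry as geo


def arc_shape(kappa, L=10.0, n=400):
    """Circular arc of curvature kappa, tangent theta(s) = kappa*s."""
    t = np.linspace(0, L, n)
    pts = np.column_stack([np.sin(kappa * t) / kappa, (1 - np.cos(kappa * t)) / kappa])
    return geo.resample_arclength(geo.FilamentShape(pts), n)


class TestResample:
    def test_straight_segment_uniform_spacing(self):
        pts = np.column_stack([np.linspace(0, 10, 7), np.zeros(7)])
        rs = geo.resample_arclength(geo.FilamentShape(pts), 11)
        assert np.allclose(np.diff(rs.s), 1.0)
        assert np.allclose(rs.points[:, 0], np.linspace(0, 10, 11))

    def test_semicircle_length(self):
        th = np.linspace(0, np.pi, 200)
        shp = geo.FilamentShape(np.column_stack([5 * np.cos(th), 5 * np.sin(th)]))
        rs = geo.resample_arclength(shp, 100)
        assert rs.length == pytest.approx(np.pi * 5, rel=5e-3)

    def test_identity_on_uniform_input(self):
        pts = np.column_stack([np.linspace(0, 5, 20), np.zeros(20)])
        shp = geo.FilamentShape(pts)
        rs = geo.resample_arclength(shp, 20)
        assert np.allclose(rs.points, shp.points)


class TestModeDecomposition:
    def test_straight_filament_all_zero(self):
        shp = ae.shape_from_modes([0.0, 0.0], L=10, n_points=60, mean_angle=1.1)
        assert np.all(np.abs(geo.decompose_modes(shp, 4)) < 1e-6)

    def test_single_mode_round_trip(self):
        shp = ae.shape_from_modes([0.0, 0.3], L=10, n_points=100)
        rec = geo.decompose_modes(shp, 6)
        assert rec[1] == pytest.approx(0.3, abs=1e-6)
        assert np.all(np.abs(np.delete(rec, 1)) < 1e-6)

    def test_round_trip_machine_precision(self):
        a = np.array([0.25, -0.4, 0.1, 0.05])
        shp = ae.shape_from_modes(a, L=7.0, n_points=200, mean_angle=-0.3)
        assert np.abs(geo.decompose_modes(shp, 4) - a).max() < 1e-12

    def test_arc_matches_analytic_cosine_coefficients(self):
        # theta(s) = kappa*s has a_n = kappa*sqrt(2/L)*L^2*((-1)^n - 1)/(n*pi)^2
        kappa, L = 0.05, 10.0
        shp = arc_shape(kappa, L, n=600)
        a = geo.decompose_modes(shp, 4)
        n = np.arange(1, 5)
        analytic = kappa * np.sqrt(2 / L) * L**2 * ((-1.0) ** n - 1) / (n * np.pi) ** 2
        assert np.allclose(a, analytic, atol=1e-4)
        # reconstructed shape matches the arc to < 1e-3 * L in position
        theta_arc, _ = geo.tangent_angles(shp)
        rec = ae.shape_from_modes(
            geo.decompose_modes(shp, 20), L=L, n_points=600,
            origin=shp.points[0], mean_angle=theta_arc.mean(),
        )
        assert np.abs(rec.points - shp.points).max() < 1e-3 * L

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        angle=st.floats(-np.pi, np.pi),
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
    )
    def test_rigid_motion_invariance(self, angle, dx, dy):
        a = np.array([0.2, -0.15])
        shp = ae.shape_from_modes(a, L=10, n_points=80)
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = geo.FilamentShape(shp.points @ R.T + [dx, dy], s=shp.s)
        assert np.abs(geo.decompose_modes(moved, 2) - a).max() < 1e-6

    def test_requires_uniform_spacing(self):
        pts = np.column_stack([np.array([0, 1, 3, 6, 10.0]), np.zeros(5)])
        with pytest.raises(ValueError, match="uniform"):
            geo.decompose_modes(geo.FilamentShape(pts), 2)

    def test_repeated_points_rejected(self):
        pts = np.array([[0, 0], [1, 0], [1, 0], [2, 0], [3, 0.0]])
        with pytest.raises(ValueError):
            geo.FilamentShape(pts)


class TestCurvature:
    def test_circle(self):
        th = np.linspace(0, np.pi, 100)
        shp = geo.FilamentShape(np.column_stack([5 * np.cos(th), 5 * np.sin(th)]))
        k = geo.local_curvature(shp, 5)
        interior = np.isfinite(k)
        assert interior.sum() == 100 - 4  # n//2 excluded at each end
        assert np.allclose(k[interior], 0.2, rtol=1e-6)

    def test_straight_line_zero(self):
        shp = geo.FilamentShape(np.column_stack([np.linspace(0, 9, 50), np.zeros(50)]))
        k = geo.local_curvature(shp, 5)
        assert np.allclose(k[np.isfinite(k)], 0.0, atol=1e-12)

    def test_parabola_apex_osculating_circle(self):
        # y = x^2/2 has kappa = |y''| / (1 + y'^2)^{3/2} = 1 at the apex
        x = np.linspace(-0.5, 0.5, 201)
        shp = geo.FilamentShape(np.column_stack([x, x**2 / 2]))
        k = geo.local_curvature(shp, 7)
        assert k[100] == pytest.approx(1.0, rel=0.02)


class TestBendingEnergy:
    def test_arc_constant_integrand_exact(self):
        kappa, L = 0.1, 10.0
        shp = arc_shape(kappa, L, n=200)
        n_window = 5
        E, eps = geo.bending_energy(shp, EI=1.0, n_window=n_window)
        k = geo.local_curvature(shp, n_window)
        good = np.isfinite(k)
        L_int = shp.s[good][-1] - shp.s[good][0]
        assert E == pytest.approx(0.5 * kappa**2 * L_int, rel=1e-6)
        assert eps == pytest.approx(E / shp.length, rel=1e-9)

    def test_straight_zero(self):
        shp = ae.shape_from_modes([0.0], L=10, n_points=50)
        E, eps = geo.bending_energy(shp)
        assert E == 0 and eps == 0

    def test_coordinate_scaling(self):
        # scaling lengths by lam: kappa -> kappa/lam, ds -> lam ds  =>  E -> E/lam
        shp = arc_shape(0.08, 10.0, n=200)
        lam = 3.0
        scaled = geo.FilamentShape(shp.points * lam)
        E1, _ = geo.bending_energy(shp, EI=1.0)
        E2, _ = geo.bending_energy(scaled, EI=1.0)
        assert E2 == pytest.approx(E1 / lam, rel=1e-3)

    def test_mode_energy_consistency_small_amplitudes(self):
        a = np.array([0.05, -0.03])
        L = 10.0
        shp = ae.shape_from_modes(a, L=L, n_points=200)
        E, _ = geo.bending_energy(shp, EI=1.0, n_window=5)
        E_modes = 0.5 * np.sum(a**2 * (np.arange(1, 3) * np.pi / L) ** 2)
        assert E == pytest.approx(E_modes, rel=0.05)

    def test_equipartition_recovery(self):
        lp, L, n_modes = 17.0, 10.0, 3
        shapes, _ = ae.thermal_filament_shapes(lp, L=L, n_modes=n_modes,
                                               n_samples=1500, seed=0)
        rec = np.array([geo.decompose_modes(s, n_modes) for s in shapes])
        n = np.arange(1, n_modes + 1)
        expect = 1.0 / (lp * (n * np.pi / L) ** 2)
        assert np.all(np.abs(rec.var(axis=0) / expect - 1) < 0.10)


class TestTraceIO:
    def _traj(self):
        shapes = [
            ae.shape_from_modes([0.1 * t], L=8, n_points=20, origin=(5, 5))
            for t in range(3)
        ]
        return geo.FilamentTrajectory("f1", [0, 1, 2], shapes)

    @pytest.mark.parametrize("fmt", ["csv", "jfilament_snakes"])
    def test_round_trip(self, fmt, tmp_path):
        path = tmp_path / f"traces.{fmt}"
        geo.write_filament_traces([self._traj()], path, fmt=fmt)
        back = geo.read_filament_traces(path, fmt=fmt)
        assert len(back) == 1
        for s0, s1 in zip(self._traj().shapes, back[0].shapes):
            assert np.allclose(s0.points, s1.points, atol=1e-5)

    def test_two_filament_ids(self, tmp_path):
        t2 = geo.FilamentTrajectory("f2", [0], [self._traj().shapes[0]])
        path = tmp_path / "traces.csv"
        geo.write_filament_traces([self._traj(), t2], path)
        back = geo.read_filament_traces(path)
        assert sorted(t.filament_id for t in back) == ["f1", "f2"]
        assert not t2.usable_for_dynamics  # single frame: no dynamics

    def test_non_monotonic_frames_rejected(self):
        shapes = self._traj().shapes
        with pytest.raises(ValueError, match="strictly increasing"):
            geo.FilamentTrajectory("bad", [0, 2, 1], shapes)

    def test_malformed_line_reports_line_number(self):
        buf = io.StringIO("# filament a\n0 0 1.0 2.0\n0 1 oops 3.0\n")
        with pytest.raises(ValueError, match="line 3"):
            geo.read_filament_traces(buf, fmt="jfilament_snakes")
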