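"""Phase-space velocity coarse-graining, the entropy integral, DFT control."""

import numpy as np
import pytest

import actent as ae
from actent.geometry import ModeTrajectory


def orbit_trajectory(omega=2.0, dt=1e-3, t_end=10.0):
    t = np.arange(0, t_end, dt)
    a = np.column_stack([np.cos(omega * t), np.sin(omega * t)])
    return ModeTrajectory(a, t, np.full(t.size, 10.0))


class TestPhaseSpaceVelocity:
    def test_orbit_velocity_tangential_with_magnitude_omega(self):
        omega = 2.0
        traj = orbit_trajectory(omega)
        fld = ae.phase_space_velocity_field([traj], bins_per_dim=12, min_count=10)
        occ = fld.counts >= 10
        speeds = np.linalg.norm(fld.velocity[occ], axis=-1)
        assert np.nanmean(speeds) == pytest.approx(omega, rel=0.02)

    def test_equilibrium_bins_consistent_with_zero(self, equilibrium_ou_ensemble):
        fld = ae.phase_space_velocity_field(equilibrium_ou_ensemble, min_count=200)
        occ = fld.counts >= 200
        v = fld.velocity[occ]
        n = fld.counts[occ]
        # bin-mean velocity has sd ~ sqrt(2*D/dt)/sqrt(n); 3-sigma envelope
        dt = 0.005
        envelope = 3 * np.sqrt(2 / dt) / np.sqrt(n)
        frac_out = np.mean(np.abs(v) > envelope[:, None])
        assert frac_out < 0.05

    def test_driven_velocity_matches_lyapunov_closed_form(self, driven_ou_ensemble):
        # v_ss(x) = Omega x with Omega = A + D C^-1 = [[0,-1],[1,0]]
        fld = ae.phase_space_velocity_field(driven_ou_ensemble, min_count=500)
        Omega = ae.ou_phase_velocity_matrix(
            ae.nonreciprocal_drift(1.0, 1.0), np.eye(2)
        )
        centers = [0.5 * (e[:-1] + e[1:]) for e in fld.edges]
        err, norm = [], []
        for i in range(fld.counts.shape[0]):
            for j in range(fld.counts.shape[1]):
                if fld.counts[i, j] < 2000:
                    continue
                x = np.array([centers[0][i], centers[1][j]])
                pred = Omega @ x
                err.append(np.linalg.norm(fld.velocity[i, j] - pred))
                norm.append(np.linalg.norm(pred))
        assert np.mean(err) < 0.25 * max(np.mean(norm), 1.0)

    def test_under_occupied_grid_rejected(self):
        t = np.arange(5) * 1.0
        traj = ModeTrajectory(np.random.default_rng(0).random((5, 2)), t, 10.0)
        with pytest.raises(ValueError, match="under-occupied"):
            ae.phase_space_velocity_field([traj], bins_per_dim=12, min_count=10)

    def test_mixed_mode_bases_rejected(self):
        t = np.arange(20) * 1.0
        a = np.random.default_rng(0).random((20, 2))
        t1 = ModeTrajectory(a, t, 10.0)
        t2 = ModeTrajectory(a, t, 10.0, basis="other")
        with pytest.raises(ValueError, match="bases"):
            ae.phase_space_velocity_field([t1, t2], min_count=1)


class TestEntropyIntegral:
    def test_deterministic_orbit_rate_omega_squared(self):
        # a_dot = v_ss  =>  integrand = |v|^2 = omega^2, so dS(1) = 4 for omega=2
        traj = orbit_trajectory(2.0)
        fld = ae.phase_space_velocity_field([traj], bins_per_dim=12, min_count=10)
        D = ae.DiffusionModel(np.eye(2))
        s = ae.entropy_production(traj, fld, D, exclude_self=False)
        i1 = np.searchsorted(s.times, 1.0)
        assert s.entropy[i1] == pytest.approx(4.0, rel=0.05)
        assert s.entropy[0] == 0.0
        assert s.coverage > 0.95

    def test_time_reversal_antisymmetry(self):
        traj = orbit_trajectory(2.0, t_end=5.0)
        fld = ae.phase_space_velocity_field([traj], min_count=5)
        D = ae.DiffusionModel(np.eye(2))
        s = ae.entropy_production(traj, fld, D, exclude_self=False)
        rev = ModeTrajectory(traj.amplitudes[::-1], traj.times, traj.lengths)
        sr = ae.entropy_production(rev, fld, D, exclude_self=False)
        assert sr.entropy[-1] == pytest.approx(-s.entropy[-1], rel=1e-9)

    def test_additivity_over_subintervals(self):
        traj = orbit_trajectory(2.0, t_end=4.0)
        fld = ae.phase_space_velocity_field([traj], min_count=5)
        D = ae.DiffusionModel(np.eye(2))
        s = ae.entropy_production(traj, fld, D, exclude_self=False)
        k = s.times.size // 2
        assert s.entropy[-1] == pytest.approx(
            s.entropy[k] + (s.entropy[-1] - s.entropy[k])
        )

    def test_scale_contract_in_diffusion(self):
        traj = orbit_trajectory(2.0, t_end=5.0)
        fld = ae.phase_space_velocity_field([traj], min_count=5)
        s1 = ae.entropy_production(traj, fld, ae.DiffusionModel(np.eye(2)),
                                   exclude_self=False)
        s3 = ae.entropy_production(traj, fld, ae.DiffusionModel(3 * np.eye(2)),
                                   exclude_self=False)
        assert s3.entropy[-1] == pytest.approx(s1.entropy[-1] / 3, rel=1e-9)

    def test_equilibrium_ensemble_slope_consistent_with_zero(
        self, equilibrium_ou_ensemble
    ):
        fld = ae.phase_space_velocity_field(equilibrium_ou_ensemble)
        D = ae.DiffusionModel(np.eye(2))
        s = [ae.entropy_production(m, fld, D) for m in equilibrium_ou_ensemble]
        slopes = np.array([x.entropy[-1] / x.times[-1] for x in s])
        # well below the driven rate of 2; not statistically distinguishable
        # from zero at the +-3 sigma level
        se = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean()) < 3 * se + 0.01

    def test_driven_ensemble_recovers_lyapunov_rate(self, driven_entropy_series):
        rate = np.mean([s.entropy[-1] / s.times[-1] for s in driven_entropy_series])
        assert rate == pytest.approx(2.0, rel=0.15)

    def test_coordinate_rotation_invariance(self, driven_ou_ensemble):
        sub = driven_ou_ensemble
        D = ae.DiffusionModel(np.eye(2))

        def rate(ts):
            fld = ae.phase_space_velocity_field(ts)
            return np.mean(
                [ae.entropy_production(m, fld, D).entropy[-1] / m.times[-1] for m in ts]
            )

        th = np.pi / 4
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = [ModeTrajectory(t.amplitudes @ R.T, t.times, t.lengths) for t in sub]
        r1, r2 = rate(sub), rate(rot)
        assert abs(r1 - r2) / r1 < 0.01


class TestSlenderRodDiffusion:
    def test_value_matches_independent_hand_formula(self):
        L, d, eta = 10.0, 7e-3, 1e-3
        dm = ae.diffusion_matrix_slender_rod(L, d, eta, temperature=1.0, n_modes=2)
        expect = (np.log(L / d) + 0.84) / (4 * np.pi * eta * L)
        assert np.allclose(np.diag(dm.D), expect)
        assert np.allclose(dm.D, np.diag(np.diag(dm.D)))

    def test_doubling_viscosity_halves_diffusion(self):
        d1 = ae.diffusion_matrix_slender_rod(10.0, viscosity_pa_s=1e-3)
        d2 = ae.diffusion_matrix_slender_rod(10.0, viscosity_pa_s=2e-3)
        assert np.allclose(d2.D, d1.D / 2)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ae.diffusion_matrix_slender_rod(0.005, diameter_um=7e-3)


class TestEnsembleCurve:
    @staticmethod
    def _series(times, incs, L=1.0):
        dS = np.concatenate([[0.0], np.cumsum(incs)])
        return ae.EntropySeries(np.asarray(times, float), dS, dS / L, 1.0, L)

    def test_single_filament_identity(self):
        s = self._series([0, 1, 2], [0.1, 0.2])
        t, c = ae.ensemble_dissipation_curve([s])
        assert np.allclose(c, [0, 0.1, 0.3])

    def test_identical_filaments_same_curve(self):
        s = self._series([0, 1, 2], [0.1, 0.2])
        t, c = ae.ensemble_dissipation_curve([s, s])
        assert np.allclose(c, [0, 0.1, 0.3])

    def test_staggered_presence_toy_table(self):
        # hand-computed: frames [0,1]: only A (0.1); [1,2]: mean(0.2, 0.4) = 0.3
        a = self._series([0, 1, 2], [0.1, 0.2])
        b = self._series([1, 2], [0.4])
        t, c = ae.ensemble_dissipation_curve([a, b])
        assert np.allclose(t, [0, 1, 2])
        assert np.allclose(c, [0, 0.1, 0.4])

    def test_temperature_scales_energy(self):
        s = self._series([0, 1], [0.5])
        _, c = ae.ensemble_dissipation_curve([s], temperature=2.0)
        assert c[-1] == pytest.approx(1.0)


class TestDetailedFluctuationTheorem:
    def test_gaussian_with_variance_twice_mean_has_unit_slope(self):
        # ln[p(x)/p(-x)] = 2 mu x / sigma^2 = x when sigma^2 = 2 mu: slope 1 exactly
        rng = np.random.default_rng(0)
        mu = 2.0
        samples = rng.normal(mu, np.sqrt(2 * mu), 50_000)
        slope, (lo, hi) = ae.check_detailed_fluctuation_theorem(samples)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert lo < 1.0 < hi

    def test_symmetric_distribution_zero_slope(self):
        rng = np.random.default_rng(1)
        slope, _ = ae.check_detailed_fluctuation_theorem(rng.normal(0, 1, 20_000))
        assert abs(slope) < 0.05

    def test_windowed_driven_entropy_obeys_dft(self, driven_entropy_series):
        w = ae.windowed_entropy_samples(driven_entropy_series, 200)
        slope, _ = ae.check_detailed_fluctuation_theorem(w)
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="500"):
            ae.check_detailed_fluctuation_theorem(np.ones(100))

    def test_one_sided_samples_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="bin pairs"):
            ae.check_detailed_fluctuation_theorem(rng.normal(50, 1, 1000))
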