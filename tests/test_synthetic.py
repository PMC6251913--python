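"""Synthetic generators: Langevin dynamics, textures, spot stacks, flows."""

import numpy as np
import pytest

import actent as ae


class TestLangevinSpec:
    def test_unstable_drift_refused(self):
        with pytest.raises(ValueError, match="not stable"):
            ae.LangevinSpec(np.array([[0.1, 0], [0, -1.0]]), np.eye(2), 0.01, 10)

    def test_asymmetric_diffusion_refused(self):
        with pytest.raises(ValueError, match="symmetric"):
            ae.LangevinSpec(-np.eye(2), np.array([[1, 0.5], [0.1, 1]]), 0.01, 10)

    def test_large_dt_warns(self):
        spec = ae.LangevinSpec(-10 * np.eye(2), np.eye(2), dt=0.05, n_steps=100, seed=0)
        with pytest.warns(UserWarning, match="dt"):
            ae.simulate_mode_dynamics(spec)


class TestModeDynamics:
    def test_equilibrium_covariance_is_identity(self):
        spec = ae.LangevinSpec(-np.eye(2), np.eye(2), dt=0.01, n_steps=50_000,
                               n_trajectories=4, seed=1)
        trajs = ae.simulate_mode_dynamics(spec)
        cov = np.cov(np.concatenate([t.amplitudes for t in trajs]).T)
        assert np.allclose(cov, np.eye(2), atol=0.08)

    def test_nonreciprocal_covariance_and_rate_oracle(self):
        # Lyapunov closed form for k=1, alpha=1, D=I: C = I/k, rate = 2 a^2/k
        A = ae.nonreciprocal_drift(1.0, 1.0)
        assert np.allclose(ae.ou_stationary_covariance(A, np.eye(2)), np.eye(2))
        assert ae.ou_entropy_rate(A, np.eye(2)) == pytest.approx(2.0)
        assert np.allclose(
            ae.ou_phase_velocity_matrix(A, np.eye(2)), [[0, -1], [1, 0]], atol=1e-12
        )
        # equilibrium has zero closed-form rate
        assert ae.ou_entropy_rate(-np.eye(2), np.eye(2)) == pytest.approx(0.0, abs=1e-10)

    def test_seed_determinism(self):
        spec = ae.LangevinSpec(-np.eye(2), np.eye(2), dt=0.01, n_steps=500,
                               n_trajectories=2, seed=42)
        a = ae.simulate_mode_dynamics(spec)
        b = ae.simulate_mode_dynamics(spec)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.amplitudes, tb.amplitudes)


class TestShapeSynthesis:
    def test_zero_modes_straight_along_reference_axis(self):
        shp = ae.shape_from_modes([0.0, 0.0], L=10, n_points=30)
        assert np.allclose(shp.points[:, 1], 0.0, atol=1e-12)
        assert shp.length == pytest.approx(10.0)


class TestTextures:
    def test_uniform_texture_recovered_by_director_field(self):
        tex = ae.TextureSpec(pattern=("uniform", np.deg2rad(30)))
        img, truth = ae.render_texture(tex)
        assert np.allclose(truth, np.deg2rad(30))
        fld = ae.compute_director_field(img, tex.pixel_size_um)
        err = np.abs(np.rad2deg(fld.angle) - 30)
        assert np.nanmax(np.minimum(err, 180 - err)) < 2.0

    @pytest.mark.parametrize("charge", [0.5, -0.5])
    def test_defect_ground_truth_winding(self, charge):
        tex = ae.TextureSpec(image_shape=(100, 100),
                             pattern=("defect", charge, (50, 50)), seed=0)
        _, truth = ae.render_texture(tex)
        # winding of the folded angle on a loop around the core
        # counterclockwise loop around the core
        ring = [(30, 50), (36, 36), (50, 30), (64, 36), (70, 50), (64, 64),
                (50, 70), (36, 64), (30, 50)]
        angs = np.array([truth[y, x] for x, y in ring])
        d = np.diff(angs)
        d = -np.mod(-d + np.pi / 2, np.pi) + np.pi / 2
        assert d.sum() == pytest.approx(charge * 2 * np.pi, abs=1e-6)

    def test_unresolvable_wavelength_rejected(self):
        with pytest.raises(ValueError, match="resolvable"):
            ae.TextureSpec(pixel_size_um=1.0, stripe_wavelength_um=1.5)

    def test_invalid_charge_rejected(self):
        with pytest.raises(ValueError, match="charge"):
            ae.TextureSpec(pattern=("defect", 1.0, (50, 50)))


class TestSpotStack:
    def test_empty_schedule_gives_noise_only(self):
        spec = ae.SpotStackSpec(count_schedule=[0, 0, 0], noise_sd=0.01, seed=0)
        stack, truth = ae.render_spot_stack(spec)
        assert stack.shape[0] == 3
        assert truth["counts"] == [0, 0, 0]
        assert stack.max() < 0.2

    def test_five_spots_counted(self):
        spec = ae.SpotStackSpec(count_schedule=[5], spot_sigma_px=2.0, seed=1)
        stack, _ = ae.render_spot_stack(spec)
        series = ae.count_intensity_peaks(stack, spec.field_area_um2,
                                          min_distance_px=5, threshold=0.5)
        assert series.counts[0] == 5

    def test_seed_determinism(self):
        spec = ae.SpotStackSpec(count_schedule=[3, 4], seed=7)
        a, _ = ae.render_spot_stack(spec)
        b, _ = ae.render_spot_stack(spec)
        assert np.array_equal(a, b)


class TestVelocityFields:
    def test_radial_divergence(self):
        fld = ae.make_velocity_field(("radial", 0.01))
        assert ae.mean_strain_rate([fld]).psi[0] == pytest.approx(-0.02, rel=1e-9)

    def test_uniform_and_shear_divergence_free(self):
        for kind in [("uniform", (1.0, -0.5)), ("shear", 0.3)]:
            fld = ae.make_velocity_field(kind)
            assert ae.mean_strain_rate([fld]).psi[0] == pytest.approx(0.0, abs=1e-12)


class TestFilamentRendering:
    def test_ridge_follows_centerline(self):
        shp = ae.shape_from_modes([0.0], L=8, n_points=30, origin=(10, 25))
        tr = ae.FilamentTrajectory("f0", [0], [shp])
        stack, meta = ae.render_filament_stack([tr], pixel_size_um=0.2, noise_sd=0)
        img = stack[0]
        ridge_rows = np.argmax(img, axis=0)[int(10 / 0.2) + 2 : int(18 / 0.2) - 2]
        assert np.all(np.abs(ridge_rows - 25 / 0.2) <= 0.5)
        assert meta["pixel_size_um"] == 0.2

    def test_two_disjoint_filaments_two_components(self):
        from scipy.ndimage import label

        s1 = ae.shape_from_modes([0.0], L=8, n_points=30, origin=(5, 10))
        s2 = ae.shape_from_modes([0.0], L=8, n_points=30, origin=(5, 40))
        trs = [ae.FilamentTrajectory(i, [0], [s]) for i, s in (("a", s1), ("b", s2))]
        stack, _ = ae.render_filament_stack(trs, pixel_size_um=0.2, noise_sd=0)
        n_comp = label(stack[0] > 0.5 * stack[0].max())[1]
        assert n_comp == 2

    def test_empty_input_empty_stack_with_metadata(self):
        stack, meta = ae.render_filament_stack([], pixel_size_um=0.1)
        assert stack.shape[0] == 0
        assert meta["pixel_size_um"] == 0.1
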