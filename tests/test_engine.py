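"""Ermak–McCammon propagator: displacement assembly, OA fast paths,
fluctuation–dissipation, determinism, Boltzmann sampling and blow-up
handling."""

import numpy as np
import pytest
from scipy import integrate

from bdhi.builders import generate_fixture
from bdhi.engine import (
    BlowUpError,
    SimulationConfig,
    SimulationState,
    apply_DF,
    draw_correlated_noise,
    propagate_step,
    refresh_caches,
    run_simulation,
)
from bdhi.forcefield import ForceFieldParams, Topology
from bdhi.hydro import (
    BeadModel,
    assemble_tensor,
    expand_oa_tensor,
    sqrt_factor,
    stokes_einstein_self,
)
from bdhi.analysis import translational_diffusion
from bdhi.units import HydroEnvironment

from conftest import random_nonoverlapping_beads

A = 5.3


class TestApplyDF:
    def test_diagonal_tensor_scales_forces(self, env):
        model = BeadModel(np.array([[0.0, 0, 0]]), A)
        tensor = assemble_tensor(model, env, "full-rpy")
        forces = np.array([[1.0, -2.0, 0.5]])
        disp = apply_DF(tensor, forces)
        np.testing.assert_allclose(disp, stokes_einstein_self(A, env) * forces)

    def test_oa_fast_path_equals_expanded_oracle(self, env, rng):
        model = random_nonoverlapping_beads(12, A, rng)
        oa = assemble_tensor(model, env, "oa-rpy")
        forces = rng.standard_normal((12, 3))
        fast = apply_DF(oa, forces)
        dense = expand_oa_tensor(oa).entries @ forces.reshape(-1)
        np.testing.assert_allclose(fast.reshape(-1), dense, rtol=1e-12)

    def test_dimension_mismatch_raises(self, env):
        model = BeadModel(np.zeros((2, 3)), A)
        tensor = assemble_tensor(model, env, "full-rpy")
        with pytest.raises(ValueError, match="mismatch"):
            apply_DF(tensor, np.zeros((3, 3)))

    def test_grid_displacement_patterns(self, env):
        # a +x force on the central bead of a 5×5 grid: the full tensor
        # displaces diagonal neighbours diagonally, the OA tensor displaces
        # every bead along +x with magnitude decaying with distance
        model, _ = generate_fixture("grid2d", nx=5, ny=5, spacing=5.3, radius=5.3)
        n = model.n_beads
        center = 12
        forces = np.zeros((n, 3))
        forces[center, 0] = 1.0

        full = apply_DF(assemble_tensor(model, env, "full-rpy"), forces)
        oa = apply_DF(assemble_tensor(model, env, "oa-rpy"), forces)

        diag_neighbor = 6  # offset (-1, -1) from the center
        # dragged both along +x and diagonally (+y), unlike the OA pattern
        assert full[diag_neighbor, 0] > 0
        assert full[diag_neighbor, 1] > 0.05 * full[diag_neighbor, 0]

        assert np.all(oa[:, 0] > 0)
        np.testing.assert_allclose(oa[:, 1:], 0.0, atol=1e-15)
        dist = np.linalg.norm(model.positions - model.positions[center], axis=1)
        order = np.argsort(dist)
        mags = oa[order, 0]
        rounded_dist = np.round(dist[order], 6)
        # strictly decreasing magnitude as distance grows (ties share values)
        for k in range(1, n):
            if rounded_dist[k] > rounded_dist[k - 1]:
                assert mags[k] < mags[k - 1]


class TestNoise:
    @pytest.mark.parametrize("kind", ["full-rpy", "oa-rpy"])
    def test_fluctuation_dissipation_covariance(self, kind, env, rng):
        model = random_nonoverlapping_beads(2, A, rng)
        tensor = assemble_tensor(model, env, kind)
        dense = (
            expand_oa_tensor(tensor).entries if kind == "oa-rpy" else tensor.entries
        )
        dt = 0.025
        draws = draw_correlated_noise(sqrt_factor(tensor), rng, 100_000, dt)
        cov = draws.T @ draws / len(draws)
        target = 2.0 * dt * dense
        err = np.linalg.norm(cov - target) / np.linalg.norm(target)
        assert err < 0.02

    def test_oa_cholesky_factor_matches_expanded_3n_factor(self, env, rng):
        model = random_nonoverlapping_beads(6, A, rng)
        oa = assemble_tensor(model, env, "oa-rpy")
        fac_n = sqrt_factor(oa).factor
        fac_3n = sqrt_factor(expand_oa_tensor(oa)).factor
        n = model.n_beads
        interleaved = np.zeros((3 * n, 3 * n))
        for al in range(3):
            interleaved[al::3, al::3] = fac_n
        np.testing.assert_allclose(fac_3n, interleaved, atol=1e-14)


class TestPropagation:
    def test_zero_forces_zero_noise_leaves_positions_unchanged(self, env, rng):
        model = random_nonoverlapping_beads(5, A, rng)
        config = SimulationConfig(
            n_steps=50, tensor_kind="full-rpy", zero_noise=True, env=env,
            save_interval=10,
        )
        traj = run_simulation(model, None, None, config)
        for frame in traj.frames:
            np.testing.assert_allclose(frame, model.positions, atol=1e-14)

    def test_reference_step_matches_compiled_path(self, env, rng):
        model = random_nonoverlapping_beads(4, A, rng)
        topo = Topology(
            n_beads=4, bonds=[[0, 1], [1, 2], [2, 3]], bond_req=[11.0, 11.0, 11.0]
        )
        params = ForceFieldParams()
        config = SimulationConfig(
            n_steps=5, tensor_update_interval=5, tensor_kind="oa-rpy",
            zero_noise=True, env=env, save_interval=1,
        )
        traj = run_simulation(model, topo, params, config)

        from bdhi.forcefield import total_energy_forces

        state = SimulationState(positions=model.positions.copy())
        refresh_caches(state, A, config)
        for _ in range(5):
            forces = total_energy_forces(
                BeadModel(state.positions, A), topo, params
            ).forces
            propagate_step(state, forces, config)
        np.testing.assert_allclose(state.positions, traj.frames[-1], atol=1e-10)

    def test_zero_steps_returns_initial_frame_only(self, env, rng):
        model = random_nonoverlapping_beads(3, A, rng)
        traj = run_simulation(model, None, None, SimulationConfig(n_steps=0, env=env))
        assert traj.n_frames == 1
        np.testing.assert_array_equal(traj.frames[0], model.positions)

    def test_same_seed_bitwise_identical(self, env):
        model, topo = generate_fixture("chain", seed=2, n=20)
        params = ForceFieldParams(eps_native=0.05)
        config = SimulationConfig(
            n_steps=2000, rng_seed=42, tensor_kind="oa-rpy", env=env, save_interval=200
        )
        t1 = run_simulation(model, topo, params, config)
        t2 = run_simulation(model, topo, params, config)
        assert np.array_equal(t1.frames, t2.frames)
        assert t1.metadata["rng_seed"] == 42

    def test_single_free_bead_msd_recovers_stokes_einstein(self, env):
        model = BeadModel(np.zeros((1, 3)), A)
        config = SimulationConfig(
            n_steps=1_000_000, tensor_kind="full-rpy", rng_seed=9, env=env,
            save_interval=10,
        )
        traj = run_simulation(model, None, None, config)
        d_est = translational_diffusion(traj, observation_interval_ns=0.001)
        d_true = stokes_einstein_self(A, env)
        assert d_est == pytest.approx(d_true, rel=0.05)

    def test_blow_up_raises_with_checkpoint(self, env):
        # a bond stretched far beyond r_eq produces a >10 Å first step
        model = BeadModel(np.array([[0.0, 0, 0], [300.0, 0, 0]]), A)
        topo = Topology(n_beads=2, bonds=[[0, 1]], bond_req=[3.8])
        config = SimulationConfig(n_steps=10, zero_noise=True, env=env)
        with pytest.raises(BlowUpError, match="step 1"):
            run_simulation(model, topo, ForceFieldParams(), config)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_steps=-1)
        with pytest.raises(ValueError):
            SimulationConfig(n_steps=1, timestep_fs=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_steps=1, tensor_kind="oseen")
        # default save interval: frames 100 ps apart at a 25 fs time step
        assert SimulationConfig(n_steps=1).save_interval == 4000


class TestStaticEquivalence:
    def test_harmonic_dimer_samples_boltzmann(self, env):
        """Equilibrium bond-length distribution of a harmonic dimer under
        OA+divergence matches the Boltzmann distribution and the full-RPY
        simulation of the same dimer."""
        r_eq, k_b = 6.0, 20.0
        model = BeadModel(np.array([[0.0, 0, 0], [r_eq, 0, 0]]), A)
        topo = Topology(n_beads=2, bonds=[[0, 1]], bond_req=[r_eq])
        params = ForceFieldParams(k_b=k_b)

        kBT = env.kBT
        weight = lambda r: r**2 * np.exp(-k_b * (r - r_eq) ** 2 / kBT)
        grid = np.linspace(r_eq - 2.0, r_eq + 2.0, 2001)
        z = integrate.simpson(weight(grid), x=grid)
        mean_b = integrate.simpson(grid * weight(grid), x=grid) / z
        var_b = integrate.simpson((grid - mean_b) ** 2 * weight(grid), x=grid) / z

        samples = {}
        for kind in ("oa-rpy", "full-rpy"):
            config = SimulationConfig(
                n_steps=400_000, tensor_kind=kind, include_divergence=True,
                rng_seed=11, env=env, save_interval=100,
            )
            traj = run_simulation(model, topo, params, config)
            r = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0], axis=1)
            samples[kind] = r[40:]  # discard equilibration

        for kind, r in samples.items():
            assert r.mean() == pytest.approx(mean_b, rel=0.01), kind
            assert r.var() == pytest.approx(var_b, rel=0.10), kind
        # the two tensor kinds agree with each other
        assert samples["oa-rpy"].mean() == pytest.approx(
            samples["full-rpy"].mean(), rel=0.01
        )


class TestUpdateIntervalSensitivity:
    def test_oa_degrades_with_stale_divergence_full_does_not(self, env):
        """Static R_gyr under full RPY is insensitive to the tensor update
        interval, while under OA the chain drifts collapse-ward as the
        cached divergence drift goes stale."""
        from bdhi.analysis import radius_of_gyration

        model, topo = generate_fixture("chain", seed=13, n=40)
        params = ForceFieldParams(eps_native=0.05)

        def mean_rgyr_tail(kind, interval):
            config = SimulationConfig(
                n_steps=400_000, tensor_kind=kind, include_divergence=True,
                tensor_update_interval=interval, rng_seed=77, env=env,
                save_interval=2000,
            )
            traj = run_simulation(model, topo, params, config)
            rg = np.array([radius_of_gyration(f) for f in traj.frames])
            return rg[len(rg) // 2 :].mean()

        oa_fresh = mean_rgyr_tail("oa-rpy", 25)
        oa_stale = mean_rgyr_tail("oa-rpy", 2000)
        assert oa_stale < oa_fresh  # collapse-ward drift with stale updates

        full_fresh = mean_rgyr_tail("full-rpy", 25)
        full_stale = mean_rgyr_tail("full-rpy", 2000)
        assert abs(full_stale - full_fresh) / full_fresh < 0.15
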