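import numpy as np
import pytest

from tctalpha import (SimulationConfig, SimulationDivergedError, child_seed,
                      draw_drives, euler_integrate, run_ensemble)
from tctalpha.simulate import (read_trajectory_csv, read_trajectory_npz,
                               write_trajectory_csv, write_trajectory_npz)


class TestDrives:
    def test_noise_off_returns_constant_means(self, params):
        cfg = SimulationConfig(noise_on=False)
        u_r, u_c = draw_drives(cfg, params, 100)
        assert np.all(u_r == 5.0) and np.all(u_c == 13.0)

    def test_zero_variance_is_constant(self, params):
        cfg = SimulationConfig(seed=7)
        p = params.replace(phi_r=0.0)
        u_r, _ = draw_drives(cfg, p, 100)
        assert np.all(u_r == p.mu_r)

    def test_sample_statistics(self, params):
        n = 100_000
        u_r, _ = draw_drives(SimulationConfig(seed=11), params, n)
        sigma = np.sqrt(params.phi_r)
        assert abs(u_r.mean() - 5.0) < 5 * sigma / np.sqrt(n)
        assert abs(u_r.var() - 0.05) < 0.1 * 0.05

    def test_density_mode_scales_variance(self, params):
        cfg = SimulationConfig(seed=11, noise_as_density=True)
        u_r, _ = draw_drives(cfg, params, 100_000)
        assert u_r.var() == pytest.approx(params.phi_r / cfg.dt, rel=0.05)

    def test_negative_variance_rejected(self, params):
        with pytest.raises(ValueError):
            params.replace(phi_r=-1.0)


class TestEuler:
    def test_retinal_block_stays_zero_without_input(self, conn, params, short_cfg):
        p = params.replace(mu_r=0.0, phi_r=0.0)
        traj = euler_integrate(p, conn, short_cfg)
        assert np.all(traj.states[:, 0] == 0.0)
        assert np.all(traj.states[:, 1] == 0.0)

    def test_step_response_matches_analytic_solution(self, conn, params):
        """x1(t) = H tau u (1 - (1 + t/tau) e^{-t/tau}) within 0.5% at dt = 0.1 ms."""
        cfg = SimulationConfig(dt=1e-4, duration=0.2, transient=0.0,
                               noise_on=False, n_realizations=1)
        traj = euler_integrate(params, conn, cfg)
        H, tau, u = params.He_thal, params.tau_e_thal, params.mu_r
        t = 10 * tau
        k = int(round(t / cfg.dt))
        analytic = H * tau * u * (1 - (1 + t / tau) * np.exp(-t / tau))
        assert traj.states[k, 0] == pytest.approx(analytic, rel=5e-3)
        assert traj.states[k, 0] == pytest.approx(0.1625, rel=5e-3)

    def test_bitwise_determinism(self, params, conn):
        cfg = SimulationConfig(duration=0.5, transient=0.1, seed=42)
        a = euler_integrate(params, conn, cfg)
        b = euler_integrate(params, conn, cfg)
        assert np.array_equal(a.v_tcr, b.v_tcr)
        assert np.array_equal(a.states, b.states)

    def test_v_tcr_recomputable_from_states(self, params, conn, short_cfg):
        from tctalpha import membrane_potentials

        traj = euler_integrate(params, conn, short_cfg)
        for i in (0, len(traj.t) // 2, -1):
            V = membrane_potentials(traj.states[i], conn)
            assert traj.v_tcr[i] == pytest.approx(V.V_tcr, abs=1e-12)

    def test_divergence_guard_names_the_step(self, params, conn, short_cfg):
        bad = params.replace(He_thal=1e15)
        with pytest.raises(SimulationDivergedError, match="step"):
            euler_integrate(bad, conn, short_cfg)

    def test_dt_accuracy_guard(self, params, conn):
        cfg = SimulationConfig(dt=1e-3, duration=1.0, transient=0.0)
        with pytest.raises(ValueError, match="dt"):
            euler_integrate(params, conn, cfg)

    def test_step_halving_convergence(self, params, conn):
        """dt = 0.1 ms is in the convergent regime.

        Settled noise-free output changes by < 1e-3 mV (sup-norm) when dt
        is halved, and the limit-cycle frequency (in the oscillatory
        C_lfi regime) changes by < 1%.
        """
        from tctalpha import cycle_frequency
        from tctalpha.spectral import set_swept_parameter

        base = SimulationConfig(dt=1e-4, duration=5.0, transient=4.0,
                                noise_on=False)
        fine = base.replace(dt=5e-5)
        v1 = euler_integrate(params, conn, base).post_transient()[1]
        v2 = euler_integrate(params, conn, fine).post_transient()[1][::2]
        assert np.max(np.abs(v1 - v2)) < 1e-3

        p, c = set_swept_parameter("C_lfi", 20.0, params, conn)
        f1 = cycle_frequency(euler_integrate(p, c, base))
        f2 = cycle_frequency(euler_integrate(p, c, fine))
        assert f1 == pytest.approx(f2, rel=0.01)


class TestEnsemble:
    def test_single_realization_uses_child_seed_zero(self, params, conn):
        cfg = SimulationConfig(duration=0.5, transient=0.1, seed=5,
                               n_realizations=1)
        [traj] = run_ensemble(params, conn, cfg)
        direct = euler_integrate(params, conn,
                                 cfg.replace(seed=child_seed(5, 0)))
        assert np.array_equal(traj.v_tcr, direct.v_tcr)

    def test_realizations_are_distinct_with_noise(self, params, conn):
        cfg = SimulationConfig(duration=0.5, transient=0.1, seed=5,
                               n_realizations=4)
        trajs = run_ensemble(params, conn, cfg)
        for i in range(4):
            for j in range(i + 1, 4):
                assert not np.array_equal(trajs[i].v_tcr, trajs[j].v_tcr)

    def test_noise_off_realizations_identical(self, params, conn):
        cfg = SimulationConfig(duration=0.5, transient=0.1, seed=5,
                               n_realizations=3, noise_on=False)
        trajs = run_ensemble(params, conn, cfg)
        assert np.array_equal(trajs[0].v_tcr, trajs[1].v_tcr)
        assert np.array_equal(trajs[0].v_tcr, trajs[2].v_tcr)

    def test_child_seeds_below_2_31(self):
        seeds = {child_seed(1, k) for k in range(100)}
        assert len(seeds) == 100
        assert all(0 <= s < 2**31 for s in seeds)


class TestTrajectoryIO:
    def test_csv_round_trip(self, params, conn, short_cfg, tmp_path):
        traj = euler_integrate(params, conn, short_cfg)
        path = tmp_path / "traj.tsv"
        write_trajectory_csv(path, traj)
        back = read_trajectory_csv(path, short_cfg)
        np.testing.assert_array_equal(back.v_tcr, traj.v_tcr)
        np.testing.assert_array_equal(back.states, traj.states)

    def test_npz_round_trip(self, params, conn, short_cfg, tmp_path):
        traj = euler_integrate(params, conn, short_cfg)
        path = tmp_path / "traj.npz"
        write_trajectory_npz(path, traj)
        back = read_trajectory_npz(path)
        np.testing.assert_array_equal(back.v_tcr, traj.v_tcr)
        np.testing.assert_array_equal(back.states, traj.states)
        assert back.config == traj.config
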