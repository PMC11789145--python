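"""Leapfrog propagation, SHAKE, thermostats, trajectory recording."""

import numpy as np
import pytest

import burnn
from burnn.hamiltonian import EnergyResult, MMPerturbedEvaluator
from burnn.md import (
    KB,
    MDOptions,
    MDState,
    ShakeError,
    apply_rattle_velocities,
    apply_shake,
    integrate_step,
    run_simulation,
    thermostat_scale,
)
from burnn.system import Atom, Configuration, SystemTopology


class _Still:
    """Zero-force evaluator."""

    def evaluate(self, config, regions=None):
        return EnergyResult(total=0.0, components={},
                            forces=np.zeros_like(config.positions))


class _Harmonic1D:
    def __init__(self, k, center):
        self.k, self.center = k, center

    def evaluate(self, config, regions=None):
        d = config.positions - self.center
        e = 0.5 * self.k * float(np.sum(d**2))
        return EnergyResult(total=e, components={"h": e}, forces=-self.k * d)


def _free_particle_topology(mass=10.0):
    return SystemTopology(
        atoms=[Atom(0, "X", mass, 0.0, 0.0, 0.0, molecule_id=0)],
        inner_molecule_ids={0},
    )


class TestIntegrateStep:
    def test_zero_forces_zero_velocities_static(self):
        topo = _free_particle_topology()
        cfg = Configuration(positions=np.array([[1.0, 1, 1]]),
                            box=np.array([5.0, 5, 5]),
                            velocities=np.zeros((1, 3)))
        state = MDState(configuration=cfg)
        new, _, _ = integrate_step(state, _Still(), topo, MDOptions(thermostat=None))
        assert np.allclose(new.configuration.positions, cfg.positions)

    def test_harmonic_oscillator_matches_cosine(self):
        # 1-D oscillator: x(t) = x0 cos(w t), checked over 10 periods
        k, m, x0 = 1000.0, 10.0, 0.05
        w = np.sqrt(k / m)
        period = 2 * np.pi / w
        dt = period / 3000
        topo = _free_particle_topology(m)
        center = np.array([2.5, 2.5, 2.5])
        cfg = Configuration(positions=(center + [x0, 0, 0])[None, :],
                            box=np.array([5.0, 5, 5]),
                            velocities=np.zeros((1, 3)))
        ev = _Harmonic1D(k, center)
        n = int(10 * period / dt)
        opts = MDOptions(dt=dt, n_steps=n, thermostat=None, sample_every=1,
                         remove_com=False, wrap=False)
        traj = run_simulation(topo, cfg, ev, opts)
        t = traj.energy_series.time.to_numpy()
        x = np.array([f.positions[0, 0] - center[0] for f in traj.frames])
        assert np.max(np.abs(x - x0 * np.cos(w * t))) < 1e-4

    def test_blowup_reports_offending_frame(self):
        topo = _free_particle_topology()
        cfg = Configuration(positions=np.array([[1.0, 1, 1]]),
                            box=np.array([5.0, 5, 5]),
                            velocities=np.zeros((1, 3)))

        class _Bad:
            def evaluate(self, config, regions=None):
                return EnergyResult(total=np.nan, components={},
                                    forces=np.full((1, 3), np.nan))

        from burnn.md import IntegrationError
        with pytest.raises(IntegrationError):
            integrate_step(MDState(configuration=cfg), _Bad(), topo,
                           MDOptions(thermostat=None))


class TestShake:
    def _diatomic(self, stretch=1.0):
        topo = SystemTopology(
            atoms=[Atom(0, "X", 12.0, 0, 0, 0, molecule_id=0),
                   Atom(1, "Y", 1.0, 0, 0, 0, molecule_id=0)],
            constraints=[(0, 1, 0.1)],
            inner_molecule_ids={0},
        )
        pos = np.array([[2.0, 2, 2], [2.0 + 0.1 * stretch, 2, 2]])
        return topo, pos

    def test_satisfied_constraints_unchanged(self):
        topo, pos = self._diatomic(1.0)
        out, n_iter = apply_shake(pos, pos.copy(), topo.constraints,
                                  topo.masses, np.array([5.0, 5, 5]))
        assert np.allclose(out, pos) and n_iter == 1

    def test_stretched_diatomic_restored(self):
        topo, pos_before = self._diatomic(1.0)
        _, pos_after = self._diatomic(1.05)     # stretched by 5%
        out, _ = apply_shake(pos_before, pos_after, topo.constraints,
                             topo.masses, np.array([5.0, 5, 5]), tol=1e-6)
        d = np.linalg.norm(out[1] - out[0])
        assert abs(d - 0.1) / 0.1 < 1e-4

    def test_empty_constraints_identity(self):
        pos = np.random.default_rng(0).uniform(0, 5, (4, 3))
        out, n_iter = apply_shake(pos, pos.copy(), [], np.ones(4),
                                  np.array([5.0, 5, 5]))
        assert np.array_equal(out, pos) and n_iter == 0

    def test_nonconvergence_raises(self):
        topo, pos = self._diatomic(1.0)
        bad = pos.copy()
        bad[1] = pos[0]  # zero bond vector: unsatisfiable along old direction
        with pytest.raises(ShakeError):
            apply_shake(pos, bad, [(0, 1, 0.1)], topo.masses,
                        np.array([5.0, 5, 5]), tol=1e-12, max_iter=5)

    def test_rattle_projects_out_bond_velocity(self):
        topo, pos = self._diatomic(1.0)
        v = np.array([[0.5, 0.1, 0.0], [-0.4, 0.0, 0.2]])
        v2 = apply_rattle_velocities(pos, v, topo.constraints, topo.masses,
                                     np.array([5.0, 5, 5]))
        bond = pos[1] - pos[0]
        assert abs(np.dot(v2[1] - v2[0], bond)) < 1e-8


class TestThermostat:
    def test_on_target_scale_is_one(self):
        rng = np.random.default_rng(0)
        masses = np.ones(50) * 10
        ndf = 150
        v = rng.normal(size=(50, 3)) * np.sqrt(KB * 300 / 10)
        from burnn.md import instantaneous_temperature
        T = instantaneous_temperature(v, masses, ndf)
        _, lam = thermostat_scale(v, masses, ndf, T, 0.1, 0.002)
        assert lam == pytest.approx(1.0)

    def test_tau_equals_dt_rescales_instantly(self):
        rng = np.random.default_rng(1)
        masses = np.ones(20) * 5
        v = rng.normal(size=(20, 3))
        from burnn.md import instantaneous_temperature
        v2, _ = thermostat_scale(v, masses, 57, 250.0, 0.002, 0.002)
        assert instantaneous_temperature(v2, masses, 57) == pytest.approx(250.0)

    def test_long_run_mean_temperature(self, toy_small):
        topo, config = toy_small
        ev = MMPerturbedEvaluator(topo, 0.0, mm_cutoff=0.9)
        opts = MDOptions(dt=0.002, n_steps=1500, thermostat="berendsen",
                         temperature=298.15, tau=0.05, seed=7, sample_every=10)
        traj = run_simulation(topo, config, ev, opts)
        mean_T = traj.energy_series.temperature.iloc[30:].mean()
        assert abs(mean_T - 298.15) / 298.15 < 0.1


class TestRunSimulation:
    def test_zero_steps_records_initial_frame_only(self, toy_small):
        topo, config = toy_small
        traj = run_simulation(topo, config, MMPerturbedEvaluator(topo, 0.0, mm_cutoff=0.9),
                              MDOptions(n_steps=0, seed=1))
        assert len(traj.frames) == 1

    def test_equal_seeds_bitwise_identical(self, toy_small):
        topo, config = toy_small
        ev = MMPerturbedEvaluator(topo, 0.0, mm_cutoff=0.9)
        opts = MDOptions(dt=0.002, n_steps=120, thermostat="andersen", seed=13,
                         sample_every=10)
        t1 = run_simulation(topo, config, ev, opts)
        t2 = run_simulation(topo, config, ev, opts)
        assert t1.energy_series.equals(t2.energy_series)

    def test_frames_and_series_aligned(self, toy_small):
        topo, config = toy_small
        traj = run_simulation(topo, config,
                              MMPerturbedEvaluator(topo, 0.0, mm_cutoff=0.9),
                              MDOptions(dt=0.002, n_steps=100, seed=3,
                                        sample_every=20))
        assert len(traj.frames) == len(traj.energy_series)
        assert traj.metadata["seed"] == 3

    def test_shake_holds_at_every_recorded_frame(self, toy_small):
        topo, config = toy_small
        from burnn.system import minimum_image_displacements
        traj = run_simulation(topo, config,
                              MMPerturbedEvaluator(topo, 0.0, mm_cutoff=0.9),
                              MDOptions(dt=0.002, n_steps=300, seed=3,
                                        sample_every=30, shake_tol=1e-6))
        for frame in traj.frames:
            for i, j, d0 in topo.constraints:
                d = np.linalg.norm(minimum_image_displacements(
                    frame.positions[j] - frame.positions[i], frame.box))
                assert abs(d - d0) / d0 < 1e-4
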