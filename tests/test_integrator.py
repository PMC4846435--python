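import numpy as np
import pytest

from patchysome.integrator import Trajectory, kinetic_energy, langevin_step, relax, run
from patchysome.params import KB, ForceFieldParams, IntegratorSettings
from patchysome.sphere_init import SurfaceConfiguration, build_configuration

from conftest import random_surface_config


def _lone_bead(radius=2.0, v=None, mass=2313.0):
    pos = np.array([[0.0, 0.0, radius]])
    vel = np.zeros((1, 3)) if v is None else np.array([v], float)
    return SurfaceConfiguration(
        radius=radius, positions=pos, species=np.zeros(1, np.int64),
        bonds=np.empty((0, 2), np.int64), velocities=vel,
        masses=np.full(1, mass))


class TestSingleStep:
    def test_cold_free_bead_stays_put(self, ff):
        cfg = _lone_bead()
        out = langevin_step(cfg, ff, IntegratorSettings(temperature=0.0, dt=0.002))
        assert np.allclose(out.positions, cfg.positions)
        assert np.allclose(out.velocities, 0.0)

    def test_two_beads_at_minimum_stationary_at_zero_T(self, ff):
        radius = 2.0
        r_min = 2 ** (1 / 6) * ff.sigma_pmpc
        half = np.arcsin(r_min / (2 * radius))
        pos = radius * np.array([
            [np.sin(half), 0, np.cos(half)], [-np.sin(half), 0, np.cos(half)]])
        cfg = SurfaceConfiguration(
            radius=radius, positions=pos, species=np.zeros(2, np.int64),
            bonds=np.empty((0, 2), np.int64), velocities=np.zeros((2, 3)),
            masses=np.full(2, 2313.0))
        out = cfg
        settings = IntegratorSettings(temperature=0.0, dt=0.002, n_steps=50,
                                      save_every=50)
        traj = run(out, ff, settings)
        assert np.allclose(traj.frames[-1].positions, pos, atol=1e-9)

    def test_moving_bead_follows_great_circle(self, ff):
        # tangential speed v on a force-free bead: geodesic arc length = v*t
        v = 0.03
        cfg = _lone_bead(radius=2.0, v=(v, 0.0, 0.0))
        settings = IntegratorSettings(temperature=0.0, t_friction=np.inf,
                                      dt=0.01, n_steps=100, save_every=100)
        traj = run(cfg, ff, settings)
        end = traj.frames[-1].positions[0]
        angle = np.arccos(np.clip(end @ cfg.positions[0] / 4.0, -1, 1))
        assert angle * 2.0 == pytest.approx(v * 1.0, rel=1e-10)
        assert np.linalg.norm(end) == pytest.approx(2.0, rel=1e-12)


class TestRun:
    def test_zero_steps_returns_initial_frame(self, ff, small_config):
        traj = run(small_config, ff, IntegratorSettings(n_steps=0))
        assert len(traj) == 1
        assert np.array_equal(traj.frames[0].positions, small_config.positions)

    def test_constraint_preserved_every_frame(self, ff):
        cfg = build_configuration(300, 1.2, 0.2, seed=8)
        cfg = relax(cfg, ff, n_iter=50)
        traj = run(cfg, ff, IntegratorSettings(dt=0.02, n_steps=400, seed=1,
                                               save_every=50))
        for f in traj.frames:
            r = np.linalg.norm(f.positions, axis=1)
            assert np.abs(r - 1.2).max() < 1e-6 * 1.2
            radial_v = np.abs(np.sum(f.positions * f.velocities, axis=1)) / 1.2
            assert radial_v.max() < 1e-8

    def test_times_strictly_increasing(self, ff, small_config):
        traj = run(small_config, ff, IntegratorSettings(dt=0.02, n_steps=300,
                                                        seed=2, save_every=100))
        assert np.all(np.diff(traj.times) > 0)

    def test_deterministic_given_seed(self, ff):
        cfg = build_configuration(200, 1.0, 0.3, seed=3)
        s = IntegratorSettings(dt=0.02, n_steps=200, seed=9, save_every=100)
        a = run(cfg, ff, s)
        b = run(cfg, ff, s)
        assert np.array_equal(a.frames[-1].positions, b.frames[-1].positions)
        assert np.array_equal(a.frames[-1].velocities, b.frames[-1].velocities)

    def test_blowup_raises_with_diagnostic(self, ff):
        cfg = build_configuration(200, 1.0, 0.0, seed=1)
        # absurd time step on the compressed lattice must abort, not hang
        with pytest.raises(RuntimeError, match="blow-up"):
            run(cfg, ff, IntegratorSettings(dt=5.0, n_steps=200, seed=0))


class TestPhysics:
    def test_free_diffusion_msd(self, ff):
        # beads far apart on a large sphere never interact: pure Langevin
        # diffusion with D = kB*T*tau/m; geodesic MSD ~ 4 D t for
        # tau << t << R^2/D
        n, radius, mass = 400, 50.0, 2313.0
        cfg = build_configuration(n, radius, 0.0, seed=21)
        t_obs = 100.0
        settings = IntegratorSettings(dt=0.05, n_steps=2000, seed=21,
                                      save_every=2000)
        traj = run(cfg, ff, settings)
        start, end = traj.frames[0].positions, traj.frames[-1].positions
        cosang = np.clip(np.sum(start * end, axis=1) / radius**2, -1, 1)
        arc = radius * np.arccos(cosang)
        msd = float(np.mean(arc**2))
        D = KB * 300.0 * 1.0 / mass
        expected = 4 * D * (t_obs - 1.0)  # ballistic correction ~tau
        assert msd == pytest.approx(expected, rel=0.15)

    def test_equipartition_two_dof(self, ff):
        cfg = build_configuration(500, 1.7, 0.2, seed=6)
        cfg = relax(cfg, ff, n_iter=100)
        settings = IntegratorSettings(dt=0.02, n_steps=4000, seed=6,
                                      save_every=200)
        traj = run(cfg, ff, settings)
        # discard thermalization, average kinetic temperature
        t_kin = traj.kinetic_temperature[5:]
        assert np.mean(t_kin) == pytest.approx(300.0, rel=0.03)

    def test_nve_energy_drift_small(self, ff):
        cfg = build_configuration(300, 1.2, 0.2, seed=4)
        cfg = relax(cfg, ff, n_iter=100)
        warm = run(cfg, ff, IntegratorSettings(dt=0.02, n_steps=500, seed=4,
                                               save_every=500))
        nve = IntegratorSettings(dt=0.002, t_friction=np.inf, n_steps=2000,
                                 seed=0, save_every=200)
        traj = run(warm.frames[-1], ff, nve)
        e = traj.potential_energy + traj.kinetic_energy
        assert abs(e[-1] - e[0]) / abs(e[0]) < 1e-4


def test_relax_reduces_energy(ff):
    from patchysome.forcefield import total_energy_forces
    cfg = build_configuration(500, 1.7, 0.2, seed=13)
    e0, _ = total_energy_forces(cfg, ff)
    e1, _ = total_energy_forces(relax(cfg, ff, n_iter=100), ff)
    assert e1 < e0
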