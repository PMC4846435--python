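"""Langevin dynamics of beads constrained to a spherical surface.

Integration uses BAOAB splitting.  The drift (A) substep moves every
bead along the great circle defined by its tangential velocity — exact
free motion on the sphere — so positions stay on the surface and speeds
are conserved to machine precision without any post-hoc rescaling.  The
kick (B) substep applies the tangential component of the force (the
discarded radial component is exactly the constraint force), and the
thermostat (O) substep applies the Ornstein-Uhlenbeck update with
per-bead friction ``gamma_i = m_i / tau`` followed by projection of the
fresh noise onto the tangent plane, which leaves each bead with two
thermal degrees of freedom (mean kinetic energy ``kB T`` per bead).

Setting ``t_friction = inf`` switches the thermostat off, giving the
NVE limit used by the energy-drift checks.

Nonbonded neighbors come from a Verlet list (cell list at cutoff +
skin) rebuilt whenever any bead has moved more than half the skin
since the last build, which makes the dynamics identical to an
every-step exact neighbor search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .forcefield import (_pair_types, cell_list_pairs, compute_forces,
                         forces_only)
from .params import KB, ForceFieldParams, IntegratorSettings
from .sphere_init import SurfaceConfiguration

#: Verlet-list skin in nm.
DEFAULT_SKIN = 0.25

#: A single-step displacement beyond this many radii aborts the run.
_BLOWUP_FRACTION = 0.25


@dataclass
class Trajectory:
    """Saved snapshots of a Langevin run plus energy/temperature series."""

    frames: list            # SurfaceConfiguration snapshots
    times: np.ndarray       # ps, strictly increasing
    settings: IntegratorSettings
    potential_energy: np.ndarray  # kJ/mol at each saved frame
    kinetic_energy: np.ndarray    # kJ/mol at each saved frame

    @property
    def kinetic_temperature(self) -> np.ndarray:
        """Instantaneous kinetic temperature (K) per saved frame (2 DOF/bead)."""
        n = self.frames[0].n
        return self.kinetic_energy / (n * KB)

    def __len__(self) -> int:
        return len(self.frames)


def kinetic_energy(config: SurfaceConfiguration) -> float:
    return float(0.5 * np.sum(config.masses[:, None] * config.velocities**2))


def _tangential(vec: np.ndarray, unit_pos: np.ndarray) -> np.ndarray:
    return vec - np.sum(vec * unit_pos, axis=1, keepdims=True) * unit_pos


@njit(cache=True, fastmath=True)
def _drift_one(px, py, pz, vx, vy, vz, radius, t):
    speed2 = vx * vx + vy * vy + vz * vz
    if speed2 <= 0.0:
        return px, py, pz, vx, vy, vz
    speed = np.sqrt(speed2)
    theta = speed * t / radius
    c = np.cos(theta)
    s = np.sin(theta)
    inv_speed = 1.0 / speed
    npx = px * c + vx * inv_speed * radius * s
    npy = py * c + vy * inv_speed * radius * s
    npz = pz * c + vz * inv_speed * radius * s
    nvx = vx * c - px / radius * speed * s
    nvy = vy * c - py / radius * speed * s
    nvz = vz * c - pz / radius * speed * s
    return npx, npy, npz, nvx, nvy, nvz


@njit(cache=True, fastmath=True)
def _baoa_kernel(pos, vel, forces, inv_m, radius, dt,
                 ou_decay, ou_sigma, noise, thermostat):
    """In-place B (half kick) + A (half drift) + O + A (half drift)."""
    half = 0.5 * dt
    inv_r2 = 1.0 / (radius * radius)
    for i in range(pos.shape[0]):
        px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
        vx, vy, vz = vel[i, 0], vel[i, 1], vel[i, 2]
        # B: tangential component of the force (radial part = constraint force)
        fdot = (forces[i, 0] * px + forces[i, 1] * py + forces[i, 2] * pz) * inv_r2
        scale = half * inv_m[i]
        vx += scale * (forces[i, 0] - fdot * px)
        vy += scale * (forces[i, 1] - fdot * py)
        vz += scale * (forces[i, 2] - fdot * pz)
        # A: half geodesic drift
        px, py, pz, vx, vy, vz = _drift_one(px, py, pz, vx, vy, vz, radius, half)
        if thermostat:
            # O: Ornstein-Uhlenbeck with tangential projection of the result
            vx = ou_decay * vx + ou_sigma[i] * noise[i, 0]
            vy = ou_decay * vy + ou_sigma[i] * noise[i, 1]
            vz = ou_decay * vz + ou_sigma[i] * noise[i, 2]
            vdot = (vx * px + vy * py + vz * pz) * inv_r2
            vx -= vdot * px
            vy -= vdot * py
            vz -= vdot * pz
        # A: half geodesic drift
        px, py, pz, vx, vy, vz = _drift_one(px, py, pz, vx, vy, vz, radius, half)
        pos[i, 0], pos[i, 1], pos[i, 2] = px, py, pz
        vel[i, 0], vel[i, 1], vel[i, 2] = vx, vy, vz


@njit(cache=True, fastmath=True)
def _monitor_kernel(pos, ref_pos, vel):
    """Max squared displacement since the last neighbor-list build and
    max squared velocity component, in one pass."""
    max_d2 = 0.0
    max_v2 = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref_pos[i, 0]
        dy = pos[i, 1] - ref_pos[i, 1]
        dz = pos[i, 2] - ref_pos[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > max_d2:
            max_d2 = d2
        for k in range(3):
            v2 = vel[i, k] * vel[i, k]
            if v2 > max_v2:
                max_v2 = v2
    return max_d2, max_v2


@njit(cache=True, fastmath=True)
def _kick_kernel(pos, vel, forces, inv_m, radius, dt):
    """In-place final B substep: tangential half kick."""
    half = 0.5 * dt
    inv_r2 = 1.0 / (radius * radius)
    for i in range(pos.shape[0]):
        px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
        fdot = (forces[i, 0] * px + forces[i, 1] * py + forces[i, 2] * pz) * inv_r2
        scale = half * inv_m[i]
        vel[i, 0] += scale * (forces[i, 0] - fdot * px)
        vel[i, 1] += scale * (forces[i, 1] - fdot * py)
        vel[i, 2] += scale * (forces[i, 2] - fdot * pz)


class _Stepper:
    """Mutable integration state: positions, velocities, forces, Verlet list."""

    def __init__(self, config: SurfaceConfiguration, params: ForceFieldParams,
                 settings: IntegratorSettings, skin: float = DEFAULT_SKIN):
        config.validate()
        self.params = params
        self.settings = settings
        self.radius = config.radius
        self.skin = skin
        # private working copies: the caller's configuration is never mutated
        self.pos = np.array(config.positions, dtype=float, order="C")
        self.vel = np.array(config.velocities, dtype=float, order="C")
        self.masses = config.masses.astype(float)
        self.kinds = np.ascontiguousarray(config.kinds(), np.int64)
        self.bonds = np.ascontiguousarray(config.bonds, np.int64)
        self.inv_m = 1.0 / self.masses
        self.rng = np.random.default_rng(settings.seed)
        self.step_index = 0
        self.thermostat = bool(np.isfinite(settings.t_friction))
        # thermostat constants (gamma = m/tau cancels: decay rate is 1/tau)
        c1 = np.exp(-settings.dt / settings.t_friction) if self.thermostat else 1.0
        self.ou_decay = float(c1)
        self.ou_sigma = np.sqrt((1.0 - c1 * c1) * KB * settings.temperature
                                / self.masses)
        self._empty_noise = np.zeros((0, 3))
        self._noise_chunk = 50
        self._noise_buf = np.empty((self._noise_chunk, len(self.masses), 3))
        self._noise_pos = self._noise_chunk
        self._max_v2 = 0.0
        self._rebuild_pairs()
        self.potential, self.forces = compute_forces(
            self.pos, self.kinds, self.bonds, self.params, self.pairs)

    def _rebuild_pairs(self):
        pi, pj = cell_list_pairs(self.pos, self.params.max_cutoff + self.skin)
        self.pairs = _pair_types(self.kinds, pi, pj)
        self._ref_pos = self.pos.copy()

    def _next_noise(self):
        # refill the buffer in chunks; the stream is identical to
        # per-step standard_normal draws for the same seed
        if self._noise_pos == self._noise_chunk:
            self.rng.standard_normal(out=self._noise_buf)
            self._noise_pos = 0
        noise = self._noise_buf[self._noise_pos]
        self._noise_pos += 1
        return noise

    def step(self, need_energy: bool = True):
        """One BAOAB step; with ``need_energy=False`` the potential energy
        of the new configuration is skipped (forces are identical)."""
        dt = self.settings.dt
        noise = self._next_noise() if self.thermostat else self._empty_noise
        _baoa_kernel(self.pos, self.vel, self.forces, self.inv_m, self.radius,
                     dt, self.ou_decay, self.ou_sigma, noise, self.thermostat)
        max_d2, self._max_v2 = _monitor_kernel(self.pos, self._ref_pos, self.vel)
        if max_d2 > (0.5 * self.skin) ** 2:
            self._rebuild_pairs()
        if need_energy:
            self.potential, self.forces = compute_forces(
                self.pos, self.kinds, self.bonds, self.params, self.pairs)
        else:
            self.potential = np.nan
            self.forces = forces_only(self.pos, self.kinds, self.bonds,
                                      self.params, self.pairs)
        _kick_kernel(self.pos, self.vel, self.forces, self.inv_m, self.radius, dt)
        self.step_index += 1
        self._check_sanity()

    def _check_sanity(self):
        max_speed = float(np.sqrt(self._max_v2)) if self.vel.size else 0.0
        max_disp = max_speed * self.settings.dt
        if not np.isfinite(max_disp) or max_disp > _BLOWUP_FRACTION * self.radius:
            raise RuntimeError(
                f"integration blow-up at step {self.step_index}: "
                f"max single-step displacement {max_disp:.3g} nm")

    def snapshot(self, template: SurfaceConfiguration) -> SurfaceConfiguration:
        cfg = template.copy()
        cfg.positions = self.pos.copy()
        cfg.velocities = self.vel.copy()
        return cfg


def relax(config: SurfaceConfiguration, params: ForceFieldParams,
          max_disp: float = 0.005, n_iter: int = 200,
          f_tol: float = 10.0) -> SurfaceConfiguration:
    """Steepest-descent relaxation with a per-iteration displacement cap.

    The freshly assigned lattice is compressed (nearest neighbors sit
    inside the PMPC sigma), so forces at step zero are large; a short
    minimization removes the worst strain before dynamics, exactly as
    an energy minimization precedes any molecular dynamics run.  Moves
    follow the tangential force, scaled so the largest bead moves
    ``max_disp`` nm, with positions renormalized to the sphere after
    every move.  Stops early once the maximum force drops below
    ``f_tol`` kJ/mol/nm.  Velocities are kept as supplied.
    """
    pos = config.positions.copy()
    kinds = config.kinds()
    for _ in range(n_iter):
        _, forces = compute_forces(pos, kinds, config.bonds, params)
        unit = pos / config.radius
        ft = _tangential(forces, unit)
        fmax = np.max(np.linalg.norm(ft, axis=1))
        if fmax < f_tol:
            break
        pos = pos + ft * (max_disp / fmax)
        pos *= config.radius / np.linalg.norm(pos, axis=1, keepdims=True)
    out = config.copy()
    out.positions = pos
    # re-project velocities onto the tangent planes of the moved positions
    out.velocities = _tangential(out.velocities, pos / config.radius)
    return out


def langevin_step(config: SurfaceConfiguration, params: ForceFieldParams,
                  settings: IntegratorSettings,
                  rng: np.random.Generator | None = None) -> SurfaceConfiguration:
    """Advance a configuration by one BAOAB Langevin step.

    Convenience single-step entry point; ``run`` amortizes force and
    neighbor-list state across steps and should be used for real runs.
    """
    stepper = _Stepper(config, params, settings)
    if rng is not None:
        stepper.rng = rng
    stepper.step()
    return stepper.snapshot(config)


def run(config: SurfaceConfiguration, params: ForceFieldParams,
        settings: IntegratorSettings, skin: float = DEFAULT_SKIN) -> Trajectory:
    """Run Langevin dynamics and return the saved trajectory.

    Frames (including the initial one) are saved every ``save_every``
    steps and at the final step.  Deterministic given
    ``settings.seed``.
    """
    stepper = _Stepper(config, params, settings, skin=skin)
    frames = [stepper.snapshot(config)]
    times = [0.0]
    pot = [stepper.potential]
    kin = [kinetic_energy(frames[0])]
    for step in range(1, settings.n_steps + 1):
        save = step % settings.save_every == 0 or step == settings.n_steps
        stepper.step(need_energy=save)
        if save:
            snap = stepper.snapshot(config)
            frames.append(snap)
            times.append(step * settings.dt)
            pot.append(stepper.potential)
            kin.append(kinetic_energy(snap))
    return Trajectory(frames=frames, times=np.array(times),
                      settings=settings,
                      potential_energy=np.array(pot),
                      kinetic_energy=np.array(kin))
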