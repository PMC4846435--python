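"""Extended XYZ readers/writers for surface configurations and trajectories.

Format: per frame, a count line, a comment line with key=value metadata
(radius, time, seed), then one line per bead:
``species x y z vx vy vz mass bond_partner`` with ``bond_partner = -1``
for unbonded beads.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .params import SPECIES_CODES, SPECIES_NAMES
from .sphere_init import SurfaceConfiguration


def _frame_lines(config: SurfaceConfiguration, time_ps: float = 0.0):
    partner = np.full(config.n, -1, int)
    for i, j in config.bonds:
        partner[i] = j
        partner[j] = i
    yield f"{config.n}\n"
    yield (f'radius={config.radius:.9g} time_ps={time_ps:.9g} '
           f'seed={config.seed}\n')
    for k in range(config.n):
        x, y, z = config.positions[k]
        vx, vy, vz = config.velocities[k]
        yield (f"{SPECIES_NAMES[int(config.species[k])]} "
               f"{x:.9g} {y:.9g} {z:.9g} "
               f"{vx:.9g} {vy:.9g} {vz:.9g} "
               f"{config.masses[k]:.9g} {partner[k]}\n")


def write_xyz(path: str | Path, config: SurfaceConfiguration,
              time_ps: float = 0.0) -> None:
    with open(path, "w") as fh:
        fh.writelines(_frame_lines(config, time_ps))


def write_trajectory_xyz(path: str | Path, trajectory) -> None:
    with open(path, "w") as fh:
        for frame, t in zip(trajectory.frames, trajectory.times):
            fh.writelines(_frame_lines(frame, float(t)))


def read_xyz(path: str | Path):
    """Read all frames; returns (configs, times)."""
    configs, times = [], []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            meta = dict(item.split("=") for item in fh.readline().split())
            species = np.empty(n, np.int64)
            pos = np.empty((n, 3))
            vel = np.empty((n, 3))
            masses = np.empty(n)
            partner = np.empty(n, np.int64)
            for k in range(n):
                parts = fh.readline().split()
                species[k] = SPECIES_CODES[parts[0]]
                pos[k] = [float(v) for v in parts[1:4]]
                vel[k] = [float(v) for v in parts[4:7]]
                masses[k] = float(parts[7])
                partner[k] = int(parts[8])
            bonds = [(i, int(partner[i])) for i in range(n)
                     if partner[i] > i]
            # normalize order: PMPC_tri first in each pair
            from .params import PMPC_TRI
            bonds = [((i, j) if species[i] == PMPC_TRI else (j, i))
                     for i, j in bonds]
            cfg = SurfaceConfiguration(
                radius=float(meta["radius"]), positions=pos, species=species,
                bonds=np.array(bonds, np.int64).reshape(-1, 2),
                velocities=vel, masses=masses, seed=int(meta.get("seed", 0)))
            configs.append(cfg)
            times.append(float(meta.get("time_ps", 0.0)))
    return configs, times
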