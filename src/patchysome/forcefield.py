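"""Interaction potentials and total forces for beads on the sphere.

Three terms make up the energy:

* same-kind pairs (PMPC/PMPC, PEO/PEO): 12-6 Lennard-Jones,
  ``U(r) = 4 eps ((sigma/r)^12 - (sigma/r)^6)``;
* unlike pairs (PMPC/PEO): pure power-law repulsion,
  ``U(r) = eps_cross (sigma_pmpc / r)^12``;
* bonded triblock pairs: flat-bottom restraint, zero below ``d_max`` and
  ``k (r - d_max)^2`` beyond it, on top of the nonbonded cross term.

Nonbonded terms are truncated and shifted to zero at
``lj_cutoff_factor`` times the pair sigma, so the energy is continuous
everywhere.  Forces are the exact negative gradients of the shifted
energy (up to the force discontinuity at the cutoff radius itself).

Distances below a 1e-3 nm floor are clamped and counted as clashes so
degenerate inputs stay finite.
"""

from __future__ import annotations

import logging

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .params import ForceFieldParams
from .sphere_init import SurfaceConfiguration

logger = logging.getLogger(__name__)

DISTANCE_FLOOR = 1e-3  # nm


# ---------------------------------------------------------------------------
# scalar / array pair potentials

def lj_pair_energy(r, eps: float, sigma: float, cutoff: float | None = None):
    """12-6 Lennard-Jones energy for same-kind bead pairs, in kJ/mol.

    With ``cutoff`` the potential is truncated and shifted to zero
    there; with ``cutoff=None`` the bare full-range value is returned.
    """
    r = np.asarray(r, float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    sr6 = (sigma / r) ** 6
    u = 4.0 * eps * (sr6 * sr6 - sr6)
    if cutoff is not None:
        src6 = (sigma / cutoff) ** 6
        u = np.where(r < cutoff, u - 4.0 * eps * (src6 * src6 - src6), 0.0)
    return u if u.ndim else float(u)


def cross_repulsion_energy(r, params: ForceFieldParams,
                           cutoff: float | None = None):
    """Repulsion between unlike beads: ``eps_cross (sigma_pmpc/r)^12``."""
    r = np.asarray(r, float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    u = params.eps_cross * (params.sigma_pmpc / r) ** 12
    if cutoff is not None:
        u = np.where(r < cutoff,
                     u - params.eps_cross * (params.sigma_pmpc / cutoff) ** 12,
                     0.0)
    return u if u.ndim else float(u)


def bond_restraint_energy(r, params: ForceFieldParams):
    """Flat-bottom restraint keeping a triblock's two beads within d_max."""
    r = np.asarray(r, float)
    if np.any(r < 0):
        raise ValueError("pair distance must be non-negative")
    excess = np.maximum(0.0, r - params.d_max)
    u = params.k_bond * excess * excess
    return u if u.ndim else float(u)


# ---------------------------------------------------------------------------
# numba kernels (per-pair loops over a precomputed neighbor list)

@njit(cache=True, fastmath=True)
def _nonbonded_kernel(pos, pair_i, pair_j, pair_type,
                      eps0, sig0, cut0, shift0,
                      eps1, sig1, cut1, shift1,
                      epsc, sigc, cutc, shiftc,
                      rfloor, forces):
    # pair_type: 0 = PMPC/PMPC LJ, 1 = PEO/PEO LJ, 2 = cross repulsion.
    # All terms depend on r only through r^2, so no sqrt is needed:
    # f = -dU/dr * r_hat = (per-r2 factor) * r_vec.
    energy = 0.0
    clashes = 0
    cut0_2 = cut0 * cut0
    cut1_2 = cut1 * cut1
    cutc_2 = cutc * cutc
    floor2 = rfloor * rfloor
    for p in range(pair_i.shape[0]):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        t = pair_type[p]
        if t == 0:
            if r2 >= cut0_2:
                continue
            eps, sig2, shift = eps0, sig0 * sig0, shift0
        elif t == 1:
            if r2 >= cut1_2:
                continue
            eps, sig2, shift = eps1, sig1 * sig1, shift1
        else:
            if r2 >= cutc_2:
                continue
            eps, sig2, shift = epsc, sigc * sigc, shiftc
        if r2 < floor2:
            r2 = floor2
            clashes += 1
        inv_r2 = 1.0 / r2
        sr2 = sig2 * inv_r2
        sr6 = sr2 * sr2 * sr2
        if t < 2:
            energy += 4.0 * eps * (sr6 * sr6 - sr6) - shift
            fmag = 4.0 * eps * (12.0 * sr6 * sr6 - 6.0 * sr6) * inv_r2
        else:
            energy += eps * sr6 * sr6 - shift
            fmag = 12.0 * eps * sr6 * sr6 * inv_r2
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return energy, clashes


@njit(cache=True, fastmath=True)
def _nonbonded_forces_kernel(pos, pair_i, pair_j, pair_type,
                             eps0, sig0, cut0,
                             eps1, sig1, cut1,
                             epsc, sigc, cutc,
                             rfloor, forces):
    # Same as _nonbonded_kernel but skips the energy accumulation (a
    # loop-carried dependency); used on integration steps whose energy
    # is never recorded.
    cut0_2 = cut0 * cut0
    cut1_2 = cut1 * cut1
    cutc_2 = cutc * cutc
    floor2 = rfloor * rfloor
    for p in range(pair_i.shape[0]):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        t = pair_type[p]
        if t == 0:
            if r2 >= cut0_2:
                continue
            eps, sig2 = eps0, sig0 * sig0
        elif t == 1:
            if r2 >= cut1_2:
                continue
            eps, sig2 = eps1, sig1 * sig1
        else:
            if r2 >= cutc_2:
                continue
            eps, sig2 = epsc, sigc * sigc
        if r2 < floor2:
            r2 = floor2
        inv_r2 = 1.0 / r2
        sr2 = sig2 * inv_r2
        sr6 = sr2 * sr2 * sr2
        if t < 2:
            fmag = 4.0 * eps * (12.0 * sr6 * sr6 - 6.0 * sr6) * inv_r2
        else:
            fmag = 12.0 * eps * sr6 * sr6 * inv_r2
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz


def _pair_types(kinds: np.ndarray, pair_i: np.ndarray, pair_j: np.ndarray):
    """Pair types (0/1/2), with pairs sorted by type for branch-friendly loops."""
    ki = kinds[pair_i]
    kj = kinds[pair_j]
    ptype = np.where(ki == kj, ki, 2).astype(np.int64)
    # bucket sort by type (cheaper than argsort on large lists)
    chunks_i, chunks_j, chunks_t = [], [], []
    for t in (0, 1, 2):
        mask = ptype == t
        chunks_i.append(pair_i[mask])
        chunks_j.append(pair_j[mask])
        chunks_t.append(ptype[mask])
    return (np.concatenate(chunks_i), np.concatenate(chunks_j),
            np.concatenate(chunks_t))


@njit(cache=True)
def _cell_pairs_kernel(pos, rlist, out_i, out_j):
    """Half neighbor list from a cell grid over the bounding box.

    Returns the number of pairs found, or -1 if the output buffers are
    too small (the caller retries with larger ones).
    """
    n = pos.shape[0]
    minx = miny = minz = 1e300
    maxx = maxy = maxz = -1e300
    for i in range(n):
        if pos[i, 0] < minx: minx = pos[i, 0]
        if pos[i, 0] > maxx: maxx = pos[i, 0]
        if pos[i, 1] < miny: miny = pos[i, 1]
        if pos[i, 1] > maxy: maxy = pos[i, 1]
        if pos[i, 2] < minz: minz = pos[i, 2]
        if pos[i, 2] > maxz: maxz = pos[i, 2]
    inv = 1.0 / rlist
    nx = int((maxx - minx) * inv) + 1
    ny = int((maxy - miny) * inv) + 1
    nz = int((maxz - minz) * inv) + 1
    ncell = nx * ny * nz
    cell = np.empty(n, np.int64)
    counts = np.zeros(ncell + 1, np.int64)
    for i in range(n):
        cx = int((pos[i, 0] - minx) * inv)
        cy = int((pos[i, 1] - miny) * inv)
        cz = int((pos[i, 2] - minz) * inv)
        c = cx + nx * (cy + ny * cz)
        cell[i] = c
        counts[c + 1] += 1
    for c in range(ncell):
        counts[c + 1] += counts[c]
    order = np.empty(n, np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        c = cell[i]
        order[fill[c]] = i
        fill[c] += 1
    rl2 = rlist * rlist
    cap = out_i.shape[0]
    cnt = 0
    # 13 half-space neighbor offsets + the home cell
    for cz in range(nz):
        for cy in range(ny):
            for cx in range(nx):
                c = cx + nx * (cy + ny * cz)
                a0 = counts[c]
                a1 = counts[c + 1]
                if a0 == a1:
                    continue
                # home cell: unordered pairs within
                for a in range(a0, a1):
                    i = order[a]
                    for b in range(a + 1, a1):
                        j = order[b]
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        if dx * dx + dy * dy + dz * dz < rl2:
                            if cnt >= cap:
                                return -1
                            out_i[cnt] = i
                            out_j[cnt] = j
                            cnt += 1
                # half shell of neighboring cells
                for off in range(13):
                    ox = _HALF_OFFSETS[off, 0]
                    oy = _HALF_OFFSETS[off, 1]
                    oz = _HALF_OFFSETS[off, 2]
                    bx = cx + ox
                    by = cy + oy
                    bz = cz + oz
                    if bx < 0 or bx >= nx or by < 0 or by >= ny or bz < 0 or bz >= nz:
                        continue
                    c2 = bx + nx * (by + ny * bz)
                    b0 = counts[c2]
                    b1 = counts[c2 + 1]
                    for a in range(a0, a1):
                        i = order[a]
                        for b in range(b0, b1):
                            j = order[b]
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            if dx * dx + dy * dy + dz * dz < rl2:
                                if cnt >= cap:
                                    return -1
                                out_i[cnt] = i
                                out_j[cnt] = j
                                cnt += 1
    return cnt


_HALF_OFFSETS = np.array(
    [(1, 0, 0), (0, 1, 0), (1, 1, 0), (-1, 1, 0),
     (0, 0, 1), (1, 0, 1), (-1, 0, 1), (0, 1, 1), (0, -1, 1),
     (1, 1, 1), (-1, 1, 1), (1, -1, 1), (-1, -1, 1)], np.int64)


def cell_list_pairs(positions: np.ndarray, cutoff: float):
    """Index pairs (unordered, i != j) within ``cutoff`` via a cell list."""
    positions = np.ascontiguousarray(positions, float)
    n = len(positions)
    cap = max(1024, 32 * n)
    while True:
        out_i = np.empty(cap, np.int64)
        out_j = np.empty(cap, np.int64)
        cnt = _cell_pairs_kernel(positions, cutoff, out_i, out_j)
        if cnt >= 0:
            return out_i[:cnt].copy(), out_j[:cnt].copy()
        cap *= 2


@njit(cache=True)
def _bond_kernel(pos, bond_i, bond_j, k_bond, d_max, forces):
    energy = 0.0
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > d_max:
            excess = r - d_max
            energy += k_bond * excess * excess
            fmag = -2.0 * k_bond * excess / r
            fx = fmag * dx
            fy = fmag * dy
            fz = fmag * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return energy


def _shift_constants(params: ForceFieldParams):
    s0 = lj_pair_energy(params.cutoff_pmpc, params.eps_pmpc, params.sigma_pmpc)
    s1 = lj_pair_energy(params.cutoff_peo, params.eps_peo, params.sigma_peo)
    sc = params.eps_cross * (params.sigma_pmpc / params.cutoff_cross) ** 12
    return s0, s1, sc


def neighbor_pairs(positions: np.ndarray, cutoff: float,
                   kinds: np.ndarray | None = None):
    """Index pairs (i < j) within ``cutoff``, optionally with pair types.

    Returns ``(pair_i, pair_j)`` or, when ``kinds`` is given,
    ``(pair_i, pair_j, pair_type)`` with type 0 = PMPC/PMPC,
    1 = PEO/PEO, 2 = cross.
    """
    tree = cKDTree(positions, balanced_tree=False, compact_nodes=False)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        pair_i = pair_j = np.empty(0, np.int64)
    else:
        pair_i = pairs[:, 0].astype(np.int64)
        pair_j = pairs[:, 1].astype(np.int64)
    if kinds is None:
        return pair_i, pair_j
    return _pair_types(np.asarray(kinds), pair_i, pair_j)


def compute_forces(positions: np.ndarray, kinds: np.ndarray,
                   bonds: np.ndarray, params: ForceFieldParams,
                   pairs=None):
    """Energy and per-bead forces for raw arrays.

    ``pairs`` may supply a precomputed neighbor list (i-array, j-array,
    type-array) covering at least every pair within the largest cutoff;
    pairs beyond their cutoff contribute nothing, so a padded Verlet
    list gives results identical to the exact list.
    """
    return _energy_forces_arrays(positions, kinds, bonds, params, pairs)


def forces_only(positions: np.ndarray, kinds: np.ndarray, bonds: np.ndarray,
                params: ForceFieldParams, pairs) -> np.ndarray:
    """Forces without the energy (fast path for the integrator)."""
    positions = np.ascontiguousarray(positions, float)
    forces = np.zeros_like(positions)
    _nonbonded_forces_kernel(
        positions, pairs[0], pairs[1], pairs[2],
        params.eps_pmpc, params.sigma_pmpc, params.cutoff_pmpc,
        params.eps_peo, params.sigma_peo, params.cutoff_peo,
        params.eps_cross, params.sigma_pmpc, params.cutoff_cross,
        DISTANCE_FLOOR, forces)
    if len(bonds):
        bonds = np.ascontiguousarray(bonds, np.int64)
        _bond_kernel(positions, bonds[:, 0], bonds[:, 1],
                     params.k_bond, params.d_max, forces)
    return forces


def _energy_forces_arrays(positions, kinds, bonds, params, pairs=None):
    positions = np.ascontiguousarray(positions, float)
    kinds = np.ascontiguousarray(kinds, np.int64)
    if pairs is None:
        pairs = neighbor_pairs(positions, params.max_cutoff, kinds)
    pair_i, pair_j, pair_type = pairs
    forces = np.zeros_like(positions)
    s0, s1, sc = _shift_constants(params)
    energy, clashes = _nonbonded_kernel(
        positions, pair_i, pair_j, pair_type,
        params.eps_pmpc, params.sigma_pmpc, params.cutoff_pmpc, s0,
        params.eps_peo, params.sigma_peo, params.cutoff_peo, s1,
        params.eps_cross, params.sigma_pmpc, params.cutoff_cross, sc,
        DISTANCE_FLOOR, forces)
    if len(bonds):
        bonds = np.ascontiguousarray(bonds, np.int64)
        energy += _bond_kernel(positions, bonds[:, 0], bonds[:, 1],
                               params.k_bond, params.d_max, forces)
    if clashes:
        logger.warning("%d bead pair(s) below the %.0e nm distance floor",
                       clashes, DISTANCE_FLOOR)
    return float(energy), forces


def total_energy_forces(config: SurfaceConfiguration,
                        params: ForceFieldParams | None = None,
                        pairs=None):
    """Total potential energy (kJ/mol) and forces (kJ/mol/nm) of a configuration."""
    params = params or ForceFieldParams()
    return compute_forces(config.positions, config.kinds(), config.bonds,
                          params, pairs=pairs)
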