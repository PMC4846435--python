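"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written as plain double loops over all
pairs, sharing no code with the package's kernels.
"""

import numpy as np


def lj_energy_shifted(r, eps, sigma, cutoff):
    if r >= cutoff:
        return 0.0
    u = 4 * eps * ((sigma / r) ** 12 - (sigma / r) ** 6)
    uc = 4 * eps * ((sigma / cutoff) ** 12 - (sigma / cutoff) ** 6)
    return u - uc


def cross_energy_shifted(r, eps, sigma, cutoff):
    if r >= cutoff:
        return 0.0
    return eps * (sigma / r) ** 12 - eps * (sigma / cutoff) ** 12


def total_energy_reference(positions, kinds, bonds, params, floor=1e-3):
    """All-pairs energy with the same truncation/shift/floor conventions."""
    n = len(positions)
    energy = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(positions[i] - positions[j]))
            r = max(r, floor)
            if kinds[i] == kinds[j]:
                if kinds[i] == 0:
                    energy += lj_energy_shifted(r, params.eps_pmpc,
                                                params.sigma_pmpc,
                                                params.cutoff_pmpc)
                else:
                    energy += lj_energy_shifted(r, params.eps_peo,
                                                params.sigma_peo,
                                                params.cutoff_peo)
            else:
                energy += cross_energy_shifted(r, params.eps_cross,
                                               params.sigma_pmpc,
                                               params.cutoff_cross)
    for i, j in bonds:
        r = float(np.linalg.norm(positions[i] - positions[j]))
        if r > params.d_max:
            energy += params.k_bond * (r - params.d_max) ** 2
    return energy


def finite_difference_forces(positions, kinds, bonds, params, energy_fn,
                             h=1e-6):
    """Central finite differences of an energy function."""
    forces = np.zeros_like(positions, dtype=float)
    for i in range(len(positions)):
        for k in range(3):
            plus = positions.copy()
            minus = positions.copy()
            plus[i, k] += h
            minus[i, k] -= h
            forces[i, k] = -(energy_fn(plus, kinds, bonds, params)
                             - energy_fn(minus, kinds, bonds, params)) / (2 * h)
    return forces


def union_find_clusters(points, cutoff):
    """Single-linkage connected components by explicit union-find."""
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) < cutoff:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[ra] = rb
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted([sorted(g) for g in groups.values()])


def brute_force_nn_minima(points):
    """Per-point shortest distance to any other point, O(N^2)."""
    pts = np.asarray(points, float)
    n = len(pts)
    minima = np.full(n, np.inf)
    for i in range(n):
        for j in range(n):
            if i != j:
                d = float(np.linalg.norm(pts[i] - pts[j]))
                minima[i] = min(minima[i], d)
    return minima
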