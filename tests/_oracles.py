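"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: exhaustive enumeration of simple
paths, double loops over frames, and grid searches over rotations.  None
of it shares code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np

TIE_TOL = 1e-12


# -- rotations ------------------------------------------------------------

def rotation_matrix(axis_angles: tuple[float, float, float]) -> np.ndarray:
    """Rotation from three successive axis rotations (x, y, z angles)."""
    ax, ay, az = axis_angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def brute_force_min_rmsd(mobile: np.ndarray, reference: np.ndarray,
                         final_step: float = 1e-3) -> float:
    """Minimum RMSD over rotations by coarse-to-fine Euler-angle search.

    Centroids are removed (translation optimum is analytic); rotations
    are searched on a grid refined down to ``final_step`` radians.
    """
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    n = len(P)

    def rmsd_at(angles):
        d = P @ rotation_matrix(angles).T - Q
        return np.sqrt((d * d).sum() / n)

    best = (0.0, 0.0, 0.0)
    best_val = rmsd_at(best)
    step = 0.5
    grid = np.arange(-np.pi, np.pi, step)
    for angles in itertools.product(grid, grid, grid):
        v = rmsd_at(angles)
        if v < best_val:
            best_val, best = v, angles
    while step > final_step:
        step /= 5.0
        offs = np.arange(-3 * step, 3 * step + step / 2, step)
        for da in itertools.product(offs, offs, offs):
            angles = tuple(b + d for b, d in zip(best, da))
            v = rmsd_at(angles)
            if v < best_val:
                best_val, best = v, angles
    return best_val


# -- correlation ----------------------------------------------------------

def brute_force_dccm(coords: np.ndarray) -> np.ndarray:
    """Double loop over atom pairs and frames for the DCCM definition."""
    F, n, _ = coords.shape
    mean = coords.mean(axis=0)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = 0.0
            vi = 0.0
            vj = 0.0
            for f in range(F):
                di = coords[f, i] - mean[i]
                dj = coords[f, j] - mean[j]
                num += di @ dj
                vi += di @ di
                vj += dj @ dj
            C[i, j] = (num / F) / np.sqrt((vi / F) * (vj / F))
    return C


def brute_force_covariance(coords: np.ndarray) -> np.ndarray:
    """Double loop over 3N coordinate pairs: Cov_ij = <d_i d_j>."""
    F = coords.shape[0]
    flat = coords.reshape(F, -1)
    mean = flat.mean(axis=0)
    m = flat.shape[1]
    cov = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            s = 0.0
            for f in range(F):
                s += (flat[f, i] - mean[i]) * (flat[f, j] - mean[j])
            cov[i, j] = s / F
    return cov


# -- shortest paths -------------------------------------------------------

def _all_shortest_paths(nodes, edges, a, b):
    """All minimum-total-weight simple paths a→b by full enumeration.

    ``edges`` maps frozenset({u, v}) -> weight.  Ties in total weight are
    kept when within TIE_TOL of the minimum.
    """
    best = np.inf
    paths = []
    others = [n for n in nodes if n not in (a, b)]
    for r in range(len(others) + 1):
        for mids in itertools.permutations(others, r):
            path = (a, *mids, b)
            total = 0.0
            ok = True
            for u, v in zip(path, path[1:]):
                w = edges.get(frozenset((u, v)))
                if w is None:
                    ok = False
                    break
                total += w
            if not ok:
                continue
            if total < best - TIE_TOL:
                best = total
                paths = [path]
            elif abs(total - best) <= TIE_TOL:
                paths.append(path)
    return best, paths


def exhaustive_betweenness(nodes, edges) -> dict:
    """C_B(i) = [2/(N(N−1))]·Σ_{a<b} τ_i^{ab}/N_ab by path enumeration."""
    nodes = list(nodes)
    N = len(nodes)
    raw = {n: 0.0 for n in nodes}
    for a, b in itertools.combinations(nodes, 2):
        best, paths = _all_shortest_paths(nodes, edges, a, b)
        if not np.isfinite(best) or not paths:
            continue
        n_ab = len(paths)
        for i in nodes:
            if i in (a, b):
                continue
            tau = sum(1 for p in paths if i in p)
            raw[i] += tau / n_ab
    scale = 2.0 / (N * (N - 1)) if N > 1 else 0.0
    return {n: v * scale for n, v in raw.items()}


def exhaustive_closeness(nodes, edges) -> dict:
    """(n_reachable−1)/Σ d(i,j) with d from exhaustive path enumeration."""
    nodes = list(nodes)
    out = {}
    for i in nodes:
        dists = []
        for j in nodes:
            if j == i:
                continue
            best, paths = _all_shortest_paths(nodes, edges, i, j)
            if np.isfinite(best):
                dists.append(best)
        total = sum(dists)
        out[i] = (len(dists) / total) if total > 0 else 0.0
    return out


def random_weighted_graph(rng: np.random.Generator, max_nodes: int = 8):
    """A random connected-ish weighted graph as (nodes, edge dict)."""
    n = int(rng.integers(4, max_nodes + 1))
    nodes = list(range(n))
    edges = {}
    for u, v in itertools.combinations(nodes, 2):
        if rng.random() < 0.55:
            edges[frozenset((u, v))] = float(rng.uniform(0.1, 2.0))
    return nodes, edges
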