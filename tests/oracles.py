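"""Independent brute-force oracles used to cross-check the implementation.

Each function re-derives a quantity by direct enumeration, deliberately
avoiding the code paths (summed-area tables, KD-trees, algebraic
simplifications) used by the package.
"""

from __future__ import annotations

import math

import numpy as np


def window_sums_direct(counts: np.ndarray, window: int) -> np.ndarray:
    """Triple-loop direct summation of window^3 blocks."""
    nx, ny, nz = counts.shape
    w = window
    out = np.zeros((nx - w + 1, ny - w + 1, nz - w + 1), dtype=np.int64)
    for i in range(nx - w + 1):
        for j in range(ny - w + 1):
            for k in range(nz - w + 1):
                out[i, j, k] = counts[i:i + w, j:j + w, k:k + w].sum()
    return out


def boltzmann_wt_expsum(
    counts: np.ndarray,
    n_frames: int,
    dV: float,
    kT: float,
    rho_bulk: float,
    top_fraction: float,
) -> float:
    """Enumerate voxels, compute each WT(dV), sort, and Boltzmann-average
    the exponentials of the n densest (zero-count voxels contribute 0)."""
    counts = np.asarray(counts).ravel()
    total = counts.size
    n = int(round(top_fraction * total))
    order = np.argsort(-counts, kind="stable")  # ties by voxel index
    selected = order[:n]
    acc = 0.0
    for idx in selected:
        c = int(counts[idx])
        if c == 0:
            continue
        rho = c / (n_frames * dV)
        wt_dv = -kT * math.log(rho / rho_bulk)
        acc += math.exp(-wt_dv / kT)
    return -kT * math.log(acc / n)


def clusters_union_find(coords: np.ndarray, link_cutoff: float) -> list[set[int]]:
    """O(n^2) union-find single-linkage components, strict < cutoff."""
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) < link_cutoff:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())


def greedy_match_direct(
    predicted: np.ndarray, experimental: np.ndarray, cutoff: float
) -> list[tuple[int, int, float]]:
    """Enumerate all pairs, sort by (distance, i, j), accept greedily."""
    pairs = []
    for i, p in enumerate(predicted):
        for j, e in enumerate(experimental):
            d = float(np.linalg.norm(p - e))
            if d <= cutoff:
                pairs.append((d, i, j))
    pairs.sort()
    used_p, used_e, out = set(), set(), []
    for d, i, j in pairs:
        if i in used_p or j in used_e:
            continue
        used_p.add(i)
        used_e.add(j)
        out.append((i, j, d))
    return out
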