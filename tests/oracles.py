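"""Brute-force oracles for the graph metrics.

Deliberately naive and independent of the implementation under test:
Floyd-Warshall for distances, explicit depth-first enumeration of all
shortest paths for geodesic counts and betweenness, direct definition-level
sums for everything else.
"""

from __future__ import annotations

import numpy as np


def fw_distances(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def enumerate_geodesics(a: np.ndarray, s: int, t: int, d: np.ndarray) -> list[tuple[int, ...]]:
    """All shortest s-t paths, by DFS constrained to distance-decreasing steps."""
    if not np.isfinite(d[s, t]) or s == t:
        return []
    paths = []

    def extend(path: tuple[int, ...]) -> None:
        v = path[-1]
        if v == t:
            paths.append(path)
            return
        for w in np.flatnonzero(a[v]):
            if d[w, t] == d[v, t] - 1:
                extend(path + (int(w),))

    extend((s,))
    return paths


def brute_metrics(a: np.ndarray) -> dict[str, np.ndarray]:
    """All seven node metrics straight from their definitions."""
    a = np.asarray(a)
    n = a.shape[0]
    d = fw_distances(a)
    degree = a.sum(axis=1).astype(float)
    cost = degree / (n - 1) if n > 1 else np.zeros(n)

    bc = np.zeros(n)
    if n >= 3:
        for s in range(n):
            for t in range(s + 1, n):
                paths = enumerate_geodesics(a, s, t, d)
                if not paths:
                    continue
                for v in range(n):
                    if v in (s, t):
                        continue
                    through = sum(1 for p in paths if v in p)
                    bc[v] += through / len(paths)
        bc = bc / ((n - 1) * (n - 2) / 2.0)

    length = np.full(n, np.nan)
    eglob = np.zeros(n)
    for i in range(n):
        dists = np.array([d[i, j] for j in range(n) if j != i])
        finite = dists[np.isfinite(dists)]
        if len(finite):
            length[i] = finite.mean()
        if n > 1:
            inv = np.where(np.isfinite(dists), 1.0 / np.where(dists == 0, np.inf, dists), 0.0)
            eglob[i] = inv.mean()

    clustering = np.zeros(n)
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            a[u, v] for ii, u in enumerate(nbrs) for v in nbrs[ii + 1 :]
        )
        clustering[i] = 2.0 * links / (k * (k - 1))
        sub = a[np.ix_(nbrs, nbrs)]
        d_sub = fw_distances(sub)
        vals = []
        for u in range(k):
            for v in range(k):
                if u != v:
                    vals.append(1.0 / d_sub[u, v] if np.isfinite(d_sub[u, v]) else 0.0)
        eloc[i] = float(np.mean(vals))

    return {
        "degree": degree,
        "cost": cost,
        "betweenness": bc,
        "avg_path_length": length,
        "global_efficiency": eglob,
        "local_efficiency": eloc,
        "clustering": clustering,
    }


def brute_sigma(a: np.ndarray) -> np.ndarray:
    """Geodesic-count matrix by explicit path enumeration."""
    n = a.shape[0]
    d = fw_distances(a)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        for t in range(n):
            if s != t:
                sigma[s, t] = len(enumerate_geodesics(a, s, t, d))
    return sigma
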