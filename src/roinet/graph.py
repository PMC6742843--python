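"""Binary-graph topology: thresholding and the seven node-level metrics.

A subject's Fisher-z matrix becomes an undirected binary graph by absolute
thresholding: an edge survives iff |z| exceeds the threshold (strictly), so
a strong anticorrelation contributes an edge exactly like a strong positive
one. For asymmetric EFF matrices a directed pass indicator is computed
first and then symmetrised (OR by default).

Node metrics, grouped the way the field groups them:

centrality
    degree k (number of neighbours), cost k/(N-1) (proportion of possible
    neighbours), and Freeman betweenness centrality (fraction of other-pair
    geodesics through the node, pair-normalised by (N-1)(N-2)/2 when
    ``betweenness_normalization="normalized"``), accumulated with Brandes'
    dependency propagation.
integration
    average path length L (mean geodesic distance to *reachable* nodes;
    undefined for isolated nodes rather than imputed) and global efficiency
    (mean inverse geodesic distance over all other nodes, with 1/inf = 0).
segregation
    clustering coefficient (proportion of neighbour pairs that are
    themselves connected) and local efficiency (global efficiency of the
    subgraph induced by the node's neighbours, the node itself excluded).

Distances and geodesic counts come from breadth-first search from every
node; everything is exact on unweighted graphs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import METRIC_COLUMNS, ConnectivityMatrix, SubjectGraph


@dataclass(frozen=True)
class GraphConfig:
    """Graph-construction and metric options.

    threshold : Fisher-z magnitude above which (strictly) an edge exists.
    eff_symmetrization : how a directed EFF pass indicator p(i,j)=|z|>tau
        becomes undirected — "OR" (edge if either direction passes, the
        default), "AND" (both), or "mean" (|mean of the two z values| > tau).
    """

    threshold: float = 0.4
    eff_symmetrization: str = "OR"
    betweenness_normalization: str = "normalized"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.eff_symmetrization not in ("OR", "AND", "mean"):
            raise ValueError("eff_symmetrization must be OR, AND or mean")
        if self.betweenness_normalization not in ("normalized", "raw"):
            raise ValueError("betweenness_normalization must be normalized or raw")


def threshold_binarize(z: ConnectivityMatrix, cfg: GraphConfig | None = None) -> SubjectGraph:
    """Binarise a z-matrix at |z| > threshold (strict; the boundary value
    itself produces no edge). NaN entries (masked diagonal, undefined ROIs)
    never produce edges."""
    cfg = cfg or GraphConfig()
    v = z.values
    with np.errstate(invalid="ignore"):
        passes = np.abs(v) > cfg.threshold
    passes &= np.isfinite(v)
    if z.kind == "FUN":
        adj = passes | passes.T  # symmetric already up to numerical noise
    elif cfg.eff_symmetrization == "OR":
        adj = passes | passes.T
    elif cfg.eff_symmetrization == "AND":
        adj = passes & passes.T
    else:  # mean
        m = (v + v.T) / 2.0
        with np.errstate(invalid="ignore"):
            adj = np.abs(m) > cfg.threshold
        adj &= np.isfinite(m)
    adj = adj.astype(np.int8)
    np.fill_diagonal(adj, 0)
    return SubjectGraph(adj, roi_labels=list(z.roi_labels))


def shortest_path_stats(graph: SubjectGraph) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted geodesic distances d and geodesic counts sigma.

    d(i, j) is the minimum link count between i and j (0 on the diagonal,
    inf when disconnected); sigma(i, j) is the number of distinct shortest
    paths. Computed by breadth-first search from every node.
    """
    a = graph.adjacency
    n = graph.n_nodes
    neighbours = [np.flatnonzero(a[i]) for i in range(n)]
    d = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        d[s, s] = 0.0
        sigma[s, s] = 1.0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in neighbours[v]:
                if np.isinf(d[s, w]):
                    d[s, w] = d[s, v] + 1
                    queue.append(w)
                if d[s, w] == d[s, v] + 1:
                    sigma[s, w] += sigma[s, v]
    return d, sigma


def _brandes_betweenness(graph: SubjectGraph) -> np.ndarray:
    """Raw betweenness: for each node v, sum over unordered pairs s<t
    (s, t != v) of the fraction of s-t geodesics through v."""
    a = graph.adjacency
    n = graph.n_nodes
    neighbours = [np.flatnonzero(a[i]) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1.0)
        dist[s] = 0.0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in neighbours[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each unordered pair counted from both endpoints


def node_centralities(
    graph: SubjectGraph, cfg: GraphConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(degree, cost, betweenness) per node.

    cost = degree / (N - 1); betweenness is pair-normalised by
    (N-1)(N-2)/2 unless cfg requests the raw Freeman sums. For N < 3
    betweenness is identically 0.
    """
    cfg = cfg or GraphConfig()
    a = graph.adjacency
    n = graph.n_nodes
    degree = a.sum(axis=1).astype(float)
    cost = degree / (n - 1) if n > 1 else np.zeros(n)
    if n < 3:
        bc = np.zeros(n)
    else:
        bc = _brandes_betweenness(graph)
        if cfg.betweenness_normalization == "normalized":
            bc = bc / ((n - 1) * (n - 2) / 2.0)
    return degree, cost, bc


def _efficiency_from_distances(d: np.ndarray) -> np.ndarray:
    """Per-node mean of 1/d over all other nodes (1/inf = 0)."""
    n = d.shape[0]
    if n < 2:
        return np.zeros(n)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def node_integration(graph: SubjectGraph) -> tuple[np.ndarray, np.ndarray]:
    """(average path length L, global efficiency) per node.

    L(i) averages d(i, j) over nodes reachable from i and is NaN for
    isolated nodes (excluded downstream, never imputed); global efficiency
    averages 1/d(i, j) over ALL other nodes, so unreachable nodes
    contribute 0.
    """
    d, _ = shortest_path_stats(graph)
    n = graph.n_nodes
    finite = np.isfinite(d)
    np.fill_diagonal(finite, False)
    n_reach = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        length = np.where(
            n_reach > 0,
            np.where(finite, d, 0.0).sum(axis=1) / np.maximum(n_reach, 1),
            np.nan,
        )
    return length, _efficiency_from_distances(d)


def node_segregation(graph: SubjectGraph) -> tuple[np.ndarray, np.ndarray]:
    """(clustering coefficient, local efficiency) per node.

    C(i) = 2 * (edges among neighbours) / (k(k-1)); local efficiency is the
    mean global efficiency of the neighbour-induced subgraph. Both are 0
    for nodes with fewer than two neighbours.
    """
    a = graph.adjacency
    n = graph.n_nodes
    clustering = np.zeros(n)
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = len(nbrs)
        if k < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        n_links = sub.sum() / 2.0
        clustering[i] = 2.0 * n_links / (k * (k - 1))
        subgraph = SubjectGraph(sub, roi_labels=[graph.roi_labels[j] for j in nbrs])
        d_sub, _ = shortest_path_stats(subgraph)
        eloc[i] = float(_efficiency_from_distances(d_sub).mean())
    return clustering, eloc


def node_metrics(graph: SubjectGraph, cfg: GraphConfig | None = None) -> pd.DataFrame:
    """All seven metrics as a DataFrame (rows = ROIs, columns in
    ``roinet.containers.METRIC_COLUMNS`` order)."""
    cfg = cfg or GraphConfig()
    degree, cost, bc = node_centralities(graph, cfg)
    length, eglob = node_integration(graph)
    clustering, eloc = node_segregation(graph)
    return pd.DataFrame(
        {
            "degree": degree,
            "cost": cost,
            "betweenness": bc,
            "avg_path_length": length,
            "global_efficiency": eglob,
            "local_efficiency": eloc,
            "clustering": clustering,
        },
        index=pd.Index(graph.roi_labels, name="roi"),
    )[list(METRIC_COLUMNS)]
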