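"""Compiled graph kernels on dense binary adjacency matrices.

The evolutionary engine evaluates ~1e5 small (N <= 90) binary graphs per
run, so the all-pairs BFS at the heart of every efficiency/path metric is
JIT-compiled with numba and free of per-node Python overhead.  The public,
validated API lives in :mod:`connectomorph.metrics`; everything here assumes
a symmetric 0/1 matrix with a zero diagonal and does not re-check it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "hop_distances",
    "global_efficiency_adj",
    "local_efficiency_adj",
    "clustering_adj",
    "path_length_adj",
    "newman_girvan_q",
]


@njit(cache=False)
def _bfs_all_pairs(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    queue = np.empty(n, np.int64)
    for s in range(n):
        dist[s, s] = 0.0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(n):
                if adj[u, v] != 0 and dist[s, v] == np.inf:
                    dist[s, v] = du + 1.0
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=False)
def _global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    dist = _bfs_all_pairs(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and dist[i, j] != np.inf:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


@njit(cache=False)
def _local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    sub = np.empty((n, n), adj.dtype)
    nbrs = np.empty(n, np.int64)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j] != 0:
                nbrs[k] = j
                k += 1
        if k < 2:
            continue
        for a in range(k):
            for b in range(k):
                sub[a, b] = adj[nbrs[a], nbrs[b]]
        total += _global_efficiency(sub[:k, :k])
    return total / n


@njit(cache=False)
def _clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j] != 0:
                k += 1
        if k < 2:
            continue
        tri = 0
        for j in range(n):
            if adj[i, j] == 0:
                continue
            for l in range(j + 1, n):
                if adj[i, l] != 0 and adj[j, l] != 0:
                    tri += 1
        total += 2.0 * tri / (k * (k - 1))
    return total / n


@njit(cache=False)
def _path_length(adj: np.ndarray) -> float:
    n = adj.shape[0]
    dist = _bfs_all_pairs(adj)
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(n):
            if i != j and dist[i, j] != np.inf:
                total += dist[i, j]
                count += 1
    if count == 0:
        return np.nan
    return total / count


def _as_u8(adj: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(adj, dtype=np.uint8)


def hop_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (inf for unreachable)."""
    return _bfs_all_pairs(_as_u8(adj))


def global_efficiency_adj(adj: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered pairs (1/inf -> 0)."""
    if adj.shape[0] < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    return float(_global_efficiency(_as_u8(adj)))


def local_efficiency_adj(adj: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph.

    Nodes with fewer than two neighbors contribute 0.
    """
    return float(_local_efficiency(_as_u8(adj)))


def clustering_adj(adj: np.ndarray) -> float:
    """Watts-Strogatz mean clustering; degree < 2 nodes contribute 0."""
    return float(_clustering(_as_u8(adj)))


def path_length_adj(adj: np.ndarray) -> float:
    """Mean shortest-path length over *reachable* ordered pairs."""
    lp = float(_path_length(_as_u8(adj)))
    if np.isnan(lp):
        raise ValueError("no reachable node pair: path length undefined")
    return lp


def newman_girvan_q(adj: np.ndarray, membership: np.ndarray) -> float:
    """Newman-Girvan modularity Q = sum_c [e_c/m - (d_c/2m)^2]."""
    a = np.asarray(adj)
    iu, ju = np.nonzero(np.triu(a, 1))
    m = iu.size
    if m == 0:
        raise ValueError("modularity undefined on an edgeless network")
    membership = np.asarray(membership)
    _, inv = np.unique(membership, return_inverse=True)
    n_comm = inv.max() + 1
    same = inv[iu] == inv[ju]
    e_c = np.bincount(inv[iu][same], minlength=n_comm).astype(float)
    deg = a.sum(axis=1).astype(float)
    d_c = np.bincount(inv, weights=deg, minlength=n_comm)
    return float((e_c / m - (d_c / (2.0 * m)) ** 2).sum())
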