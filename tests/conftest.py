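"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
modularity by explicit double loop, shortest-path measures by BFS /
path-count dynamic programming, KS distance by an ECDF sweep.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hopfnet.connectome import StructuralConnectome, default_partition
from hopfnet.dynamics import ModelParameters, SimulationConfig


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def small_connectome() -> StructuralConnectome:
    """12-node, 3-system connectome with moderate modular coupling."""
    rng = np.random.default_rng(7)
    n = 12
    part = default_partition(n, 3)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = 0.8 if part[i] == part[j] else 0.25
            if rng.random() < p:
                w[i, j] = w[j, i] = rng.lognormal(-0.5, 0.4)
    return StructuralConnectome(w, [f"R{i:02d}" for i in range(n)], part)


@pytest.fixture(scope="session")
def fast_cfg() -> SimulationConfig:
    """Short, coarse simulation for unit tests (~100 output samples)."""
    return SimulationConfig(dt=0.04, duration=30 + 99 * 0.72 + 0.04, burn_in=30.0,
                            tr=0.72, seed=11, record_frequencies=False)


@pytest.fixture(scope="session")
def base_params(small_connectome) -> ModelParameters:
    rng = np.random.default_rng(3)
    omega0 = 2 * np.pi * rng.uniform(0.03, 0.09, small_connectome.n_nodes) * 0.4
    return ModelParameters(a=0.04, omega0=omega0, G=0.01, lam=0.4, m=0.14, beta=0.02)


# ---------------------------------------------------------------- oracles
def oracle_modularity(w: np.ndarray, partition) -> float:
    """Literal double-sum modularity with clipped negative weights."""
    w = np.clip(np.asarray(w, dtype=float), 0, None).copy()
    np.fill_diagonal(w, 0.0)
    part = list(partition)
    v = w.sum()
    s = w.sum(axis=1)
    q = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(n):
            if part[i] == part[j]:
                q += w[i, j] - s[i] * s[j] / v
    return q / v


def oracle_bfs_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs hop distances by breadth-first search; inf if unreachable."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        seen = {s}
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adj[u]):
                    if v not in seen:
                        seen.add(int(v))
                        dist[s, v] = d
                        nxt.append(int(v))
            frontier = nxt
    return dist


def oracle_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    dist = oracle_bfs_distances(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def oracle_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        if nbrs.size >= 2:
            out[v] = oracle_global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return out


def oracle_path_counts(adj: np.ndarray):
    """Number of shortest paths between all pairs (binary graph)."""
    n = adj.shape[0]
    dist = oracle_bfs_distances(adj)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(dist[s])
        for v in order:
            if v == s or not np.isfinite(dist[s, v]):
                continue
            preds = [u for u in np.flatnonzero(adj[:, v]) if dist[s, u] + 1 == dist[s, v]]
            sigma[s, v] = sum(sigma[s, u] for u in preds)
    return dist, sigma


def oracle_betweenness(adj: np.ndarray) -> np.ndarray:
    """Pair-count betweenness: sum over unordered (s, t) of the fraction of
    shortest s-t paths passing through v."""
    n = adj.shape[0]
    dist, sigma = oracle_path_counts(adj)
    btw = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if dist[s, v] + dist[v, t] == dist[s, t]:
                btw[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return btw


def oracle_closeness(adj: np.ndarray) -> np.ndarray:
    """Inverse mean BFS distance over reachable nodes."""
    n = adj.shape[0]
    dist = oracle_bfs_distances(adj)
    out = np.zeros(n)
    for v in range(n):
        d = dist[v][np.isfinite(dist[v])]
        d = d[d > 0]
        if d.size:
            out[v] = d.size / d.sum()
    return out


def oracle_ks(a: np.ndarray, b: np.ndarray) -> float:
    """Supremum ECDF difference by sweeping every sample point."""
    pts = np.concatenate([a, b])
    best = 0.0
    for x in pts:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


def random_binary_graph(rng: np.random.Generator, n: int, p: float = 0.4) -> np.ndarray:
    adj = (rng.random((n, n)) < p).astype(int)
    adj = np.triu(adj, 1)
    return adj + adj.T
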