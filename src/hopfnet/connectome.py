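"""Structural connectome containers, synthetic connectome generation, and
group-representative construction.

The structural connectome is a weighted undirected graph between cortical
regions (weights in arbitrary streamline-density-like units).  A
group-representative matrix is built from a stack of subject matrices with a
consistency rule (an edge is kept when it is present in at least a given
fraction of subjects) and its weight distribution is then rank-remapped onto
a Gaussian, which is the conventional preprocessing for coupling matrices in
whole-brain oscillator models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_SYSTEMS = ("DM", "LIM", "dATT/CONT", "SAL/vATT", "SOM", "VIS")

__all__ = [
    "StructuralConnectome",
    "SubjectConnectomeStack",
    "DEFAULT_SYSTEMS",
    "generate_subject_connectomes",
    "generate_hub_connectome",
    "build_group_connectome",
    "gaussian_resample_weights",
    "structural_centralities",
    "unity_normalize",
]


def _check_square_symmetric(w: np.ndarray, name: str = "weights") -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError(f"{name} must be finite")
    if not np.allclose(w, w.T, atol=1e-9):
        raise ValueError(f"{name} must be symmetric")
    return 0.5 * (w + w.T)


@dataclass
class StructuralConnectome:
    """Symmetric nonnegative weight matrix with region labels and a
    region -> functional-system partition."""

    weights: np.ndarray
    labels: list[str]
    partition: list[str] | None = None

    def __post_init__(self) -> None:
        w = _check_square_symmetric(self.weights)
        if np.any(w < 0):
            raise ValueError("connectome weights must be nonnegative")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != w.shape[0]:
            raise ValueError("label count does not match matrix size")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")
        if self.partition is not None:
            self.partition = [str(x) for x in self.partition]
            if len(self.partition) != w.shape[0]:
                raise ValueError("partition must cover every node")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def copy(self) -> "StructuralConnectome":
        return StructuralConnectome(
            self.weights.copy(),
            list(self.labels),
            None if self.partition is None else list(self.partition),
        )


@dataclass
class SubjectConnectomeStack:
    """Ordered collection of subject-level connectome matrices sharing one
    region labelling."""

    subjects: list[np.ndarray]
    labels: list[str]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("empty subject stack")
        mats = []
        n = None
        for k, m in enumerate(self.subjects):
            m = _check_square_symmetric(m, name=f"subject {k}")
            np.fill_diagonal(m, 0.0)
            if n is None:
                n = m.shape[0]
            elif m.shape[0] != n:
                raise ValueError("all subject matrices must share one shape")
            mats.append(m)
        self.subjects = mats
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != n:
            raise ValueError("label count does not match matrix size")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_nodes(self) -> int:
        return self.subjects[0].shape[0]

    def as_array(self) -> np.ndarray:
        return np.stack(self.subjects, axis=0)


def default_labels(n_nodes: int) -> list[str]:
    return [f"R{i:02d}" for i in range(n_nodes)]


def default_partition(n_nodes: int, n_systems: int) -> list[str]:
    """Contiguous near-equal blocks of nodes mapped onto the six canonical
    functional systems (cycled / user-extended beyond six)."""
    if n_systems < 1:
        raise ValueError("n_systems must be positive")
    names = [
        DEFAULT_SYSTEMS[i] if i < len(DEFAULT_SYSTEMS) else f"SYS{i}"
        for i in range(n_systems)
    ]
    sizes = np.full(n_systems, n_nodes // n_systems, dtype=int)
    sizes[: n_nodes % n_systems] += 1
    out: list[str] = []
    for name, size in zip(names, sizes):
        out.extend([name] * int(size))
    return out


def generate_subject_connectomes(
    n_nodes: int = 68,
    n_subjects: int = 20,
    n_systems: int = 6,
    density: float = 0.3,
    dropout: float = 0.2,
    seed: int = 0,
    within_between_ratio: float = 4.0,
) -> SubjectConnectomeStack:
    """Synthetic subject connectomes with modular topology.

    A group template is drawn first: node pairs within a functional system
    connect with higher probability than pairs between systems (odds set by
    ``within_between_ratio``), and template edges carry log-normal positive
    weights.  Each subject is the template with an independently chosen
    ``dropout`` fraction of its edges zeroed, emulating subject-varying edge
    presence in tractography.
    """
    if n_nodes < 4:
        raise ValueError("n_nodes must be at least 4")
    if n_subjects < 1 or n_systems < 1:
        raise ValueError("counts must be positive")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")

    rng = np.random.default_rng(seed)
    part = np.asarray(default_partition(n_nodes, n_systems))
    iu, ju = np.triu_indices(n_nodes, k=1)
    within = part[iu] == part[ju]
    n_within = int(within.sum())
    n_between = int((~within).sum())
    # choose p_between so expected overall density matches `density`
    p_between = density * (n_within + n_between) / (
        within_between_ratio * n_within + n_between
    )
    p_within = min(1.0, within_between_ratio * p_between)
    p_edge = np.where(within, p_within, p_between)

    template_mask = rng.random(iu.size) < p_edge
    template_w = np.zeros(iu.size)
    template_w[template_mask] = rng.lognormal(mean=0.0, sigma=0.5, size=int(template_mask.sum()))

    edge_idx = np.flatnonzero(template_mask)
    n_drop = int(round(dropout * edge_idx.size))
    subjects = []
    for _ in range(n_subjects):
        w = template_w.copy()
        if n_drop > 0:
            dropped = rng.choice(edge_idx, size=n_drop, replace=False)
            w[dropped] = 0.0
        mat = np.zeros((n_nodes, n_nodes))
        mat[iu, ju] = w
        mat[ju, iu] = w
        subjects.append(mat)
    return SubjectConnectomeStack(subjects, default_labels(n_nodes))


def generate_hub_connectome(
    n_nodes: int = 68,
    n_hubs: int = 8,
    n_systems: int = 6,
    seed: int = 0,
    periphery_density: float = 0.08,
) -> StructuralConnectome:
    """Core-periphery connectome dominated by a small hub core.

    Hubs connect densely to everything (core and periphery); periphery nodes
    connect to each other only sparsely, so most communication routes run
    through the core.  Used for attack-strategy experiments where hub
    removal should be maximally disruptive.
    """
    if not 1 <= n_hubs < n_nodes:
        raise ValueError("need 1 <= n_hubs < n_nodes")
    rng = np.random.default_rng(seed)
    w = np.zeros((n_nodes, n_nodes))
    hubs = np.arange(n_hubs)
    # dense, strong core and hub-periphery spokes
    for h in hubs:
        for j in range(n_nodes):
            if j == h:
                continue
            strength = 2.0 if j < n_hubs else 1.0
            w[h, j] = w[j, h] = strength * rng.lognormal(0.0, 0.25)
    # sparse weak periphery-periphery edges
    iu, ju = np.triu_indices(n_nodes, k=1)
    periph = (iu >= n_hubs) & (ju >= n_hubs)
    keep = periph & (rng.random(iu.size) < periphery_density)
    vals = 0.15 * rng.lognormal(0.0, 0.25, size=int(keep.sum()))
    w[iu[keep], ju[keep]] = vals
    w[ju[keep], iu[keep]] = vals
    return StructuralConnectome(
        w, default_labels(n_nodes), default_partition(n_nodes, n_systems)
    )


def build_group_connectome(
    stack: SubjectConnectomeStack,
    consistency: float = 0.6,
    partition: list[str] | None = None,
) -> StructuralConnectome:
    """Group-representative connectome under the edge-consistency rule.

    An edge is retained when the fraction of subjects with a nonzero value
    is at least ``consistency``; its group weight is the mean of that edge's
    values across *all* subjects (zeros of non-expressing subjects
    included).  All other edges are zero.
    """
    if not 0 < consistency <= 1:
        raise ValueError("consistency must be in (0, 1]")
    arr = stack.as_array()
    frac_nonzero = (arr != 0).mean(axis=0)
    mean_w = arr.mean(axis=0)
    group = np.where(frac_nonzero >= consistency, mean_w, 0.0)
    np.fill_diagonal(group, 0.0)
    return StructuralConnectome(group, list(stack.labels), partition)


def gaussian_resample_weights(
    c: StructuralConnectome, mu: float = 0.5, sigma: float = 0.15
) -> StructuralConnectome:
    """Rank-remap the nonzero undirected edge weights onto Gaussian
    quantiles Phi^-1(rank / (M + 1)) * sigma + mu.

    Zero edges stay zero and the rank order of weights is preserved; ties
    are broken by the stable (i, j) index order.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    w = c.weights
    iu, ju = np.triu_indices(c.n_nodes, k=1)
    vals = w[iu, ju]
    nz = np.flatnonzero(vals)
    m = nz.size
    if m == 0:
        raise ValueError("connectome has no nonzero edges")
    order = np.argsort(vals[nz], kind="stable")
    ranks = np.empty(m, dtype=float)
    ranks[order] = np.arange(1, m + 1)
    new_vals = stats.norm.ppf(ranks / (m + 1.0)) * sigma + mu
    out = np.zeros_like(w)
    out[iu[nz], ju[nz]] = new_vals
    out = out + out.T
    return StructuralConnectome(out, list(c.labels), c.partition)


def unity_normalize(x: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); all zeros when the range is degenerate."""
    x = np.asarray(x, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if not np.isfinite(hi - lo) or hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _to_graph(c: StructuralConnectome) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(c.n_nodes))
    iu, ju = np.triu_indices(c.n_nodes, k=1)
    for i, j in zip(iu, ju):
        wij = c.weights[i, j]
        if wij > 0:
            g.add_edge(int(i), int(j), weight=float(wij), length=1.0 / float(wij))
    return g


def _binary_local_efficiency(adj: np.ndarray) -> np.ndarray:
    """Per-node local efficiency on binary support: global efficiency of the
    subgraph induced by the node's neighbours."""
    from .graphtools import _pairwise_efficiency_sum

    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        if nbrs.size < 2:
            out[v] = 0.0
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        k = nbrs.size
        out[v] = _pairwise_efficiency_sum(sub) / (k * (k - 1))
    return out


def structural_centralities(c: StructuralConnectome) -> pd.DataFrame:
    """Nodal centrality table: strength, degree, betweenness, closeness,
    weighted clustering, binary local efficiency, and the composite hub
    score.

    Shortest paths use the edge length 1/weight.  Closeness is the inverse
    mean shortest-path distance over reachable nodes; pairs in different
    components are excluded from betweenness.  The hub score is the mean of
    the unity-normalized strength, betweenness and closeness.
    """
    if c.n_nodes == 0:
        raise ValueError("empty connectome")
    w = c.weights
    adj = (w > 0).astype(int)
    np.fill_diagonal(adj, 0)
    strength = w.sum(axis=1)
    degree = adj.sum(axis=1)
    g = _to_graph(c)
    btw = nx.betweenness_centrality(g, weight="length", normalized=False)
    betweenness = np.array([btw[i] for i in range(c.n_nodes)])
    closeness = np.zeros(c.n_nodes)
    for v in range(c.n_nodes):
        dists = nx.single_source_dijkstra_path_length(g, v, weight="length")
        dists = {u: d for u, d in dists.items() if u != v}
        if dists:
            closeness[v] = len(dists) / sum(dists.values())
    clustering_map = nx.clustering(g, weight="weight")
    clustering = np.array([clustering_map[i] for i in range(c.n_nodes)])
    local_eff = _binary_local_efficiency(adj)
    hub = (
        unity_normalize(strength)
        + unity_normalize(betweenness)
        + unity_normalize(closeness)
    ) / 3.0
    return pd.DataFrame(
        {
            "strength": strength,
            "degree": degree.astype(float),
            "betweenness": betweenness,
            "closeness": closeness,
            "clustering": clustering,
            "local_efficiency": local_eff,
            "hub_score": hub,
        },
        index=pd.Index(c.labels, name="region"),
    )
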