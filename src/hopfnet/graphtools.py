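"""Binary-graph utilities for functional connectivity matrices.

Covers thresholding/binarization, giant component size, global and local
efficiency with degree-preserving null normalization, per-system
segregation, and the accuracy/precision procedure used to select an
absolute binarization threshold by comparing simulated against reference FC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "BinaryGraph",
    "ThresholdReport",
    "threshold_binarize",
    "giant_component_fraction",
    "global_efficiency",
    "local_efficiency",
    "normalize_by_null",
    "system_segregation",
    "select_binarization_threshold",
]


@dataclass
class BinaryGraph:
    adjacency: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        a = (a != 0).astype(np.int8)
        np.fill_diagonal(a, 0)
        self.adjacency = a
        if self.labels is None:
            self.labels = [str(i) for i in range(a.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def threshold_binarize(values: np.ndarray, threshold: float, labels=None) -> BinaryGraph:
    """Edge present iff the (absolute-scale) FC value is >= threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    v = np.asarray(values, dtype=float)
    adj = (v >= threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    adj = adj & adj.T  # symmetry safeguard for near-symmetric input
    return BinaryGraph(adj, labels)


def giant_component_fraction(g: BinaryGraph) -> float:
    """Size of the largest connected component divided by N (undirected)."""
    n_comp, comp = connected_components(g.adjacency, directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    return float(sizes.max()) / g.n_nodes


def _pairwise_efficiency_sum(adj: np.ndarray) -> float:
    """Sum over ordered node pairs of 1/d(i,j), 0 for unreachable pairs."""
    if adj.shape[0] < 2:
        return 0.0
    d = shortest_path(adj.astype(float), method="D", directed=False, unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum())


def global_efficiency(g: BinaryGraph) -> float:
    """Mean over ordered node pairs of inverse shortest-path length."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return _pairwise_efficiency_sum(np.asarray(g.adjacency)) / (n * (n - 1))


def local_efficiency(g: BinaryGraph, nodes=None) -> tuple[np.ndarray, float]:
    """Per-node local efficiency (global efficiency of the neighbour-induced
    subgraph) and the mean over the requested node subset."""
    adj = np.asarray(g.adjacency)
    n = g.n_nodes
    if nodes is None:
        nodes = np.arange(n)
    nodes = np.asarray(nodes, dtype=int)
    if nodes.size == 0:
        raise ValueError("node subset must be nonempty")
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        if nbrs.size < 2:
            continue
        k = nbrs.size
        out[v] = _pairwise_efficiency_sum(adj[np.ix_(nbrs, nbrs)]) / (k * (k - 1))
    return out, float(out[nodes].mean())


def normalize_by_null(
    g: BinaryGraph,
    measure: str = "global_efficiency",
    n_null: int = 20,
    seed: int = 0,
    system_nodes=None,
    swaps_per_edge: int = 10,
) -> float:
    """Observed measure divided by its mean over degree-preserving rewired
    (double-edge-swap) null graphs.

    ``measure`` is ``"global_efficiency"`` or ``"local_efficiency"`` (the
    latter averaged over ``system_nodes``).  Graphs too sparse to rewire
    return 1.0 with a warning.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if measure == "global_efficiency":
        observed = global_efficiency(g)
        evaluate = lambda bg: global_efficiency(bg)  # noqa: E731
    elif measure == "local_efficiency":
        observed = local_efficiency(g, system_nodes)[1]
        evaluate = lambda bg: local_efficiency(bg, system_nodes)[1]  # noqa: E731
    else:
        raise ValueError(f"unknown measure {measure!r}")

    gx = nx.from_numpy_array(np.asarray(g.adjacency))
    n_edges = gx.number_of_edges()
    if n_edges < 2:
        warnings.warn("graph too sparse for degree-preserving rewiring; returning 1.0")
        return 1.0
    if n_edges == g.n_nodes * (g.n_nodes - 1) // 2:
        return 1.0  # complete graph: rewiring is the identity
    rng = np.random.default_rng(seed)
    null_vals = []
    for _ in range(n_null):
        gnull = gx.copy()
        try:
            nx.double_edge_swap(
                gnull,
                nswap=swaps_per_edge * n_edges,
                max_tries=20 * swaps_per_edge * n_edges,
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXException:
            pass  # fewer swaps achieved than requested; degrees still preserved
        adj = nx.to_numpy_array(gnull, nodelist=range(g.n_nodes))
        null_vals.append(evaluate(BinaryGraph(adj, g.labels)))
    null_mean = float(np.mean(null_vals))
    if null_mean == 0:
        warnings.warn("null-model mean is zero; returning 1.0")
        return 1.0
    return observed / null_mean


def system_segregation(values: np.ndarray, partition) -> dict[str, float]:
    """Per-system within-versus-between FC contrast.

    For each system: (mean within-system off-diagonal FC - mean FC between
    that system and all other nodes) / mean within-system FC.  NaN when the
    within-system mean is nonpositive.
    """
    v = np.asarray(values, dtype=float)
    part = np.asarray([str(p) for p in partition])
    systems = list(dict.fromkeys(part))
    out: dict[str, float] = {}
    for s in systems:
        inside = np.flatnonzero(part == s)
        outside = np.flatnonzero(part != s)
        if inside.size < 2:
            raise ValueError(f"system {s!r} must contain at least 2 nodes")
        block = v[np.ix_(inside, inside)]
        within = block[~np.eye(inside.size, dtype=bool)].mean()
        between = v[np.ix_(inside, outside)].mean() if outside.size else 0.0
        out[s] = (within - between) / within if within > 0 else float("nan")
    return out


@dataclass
class ThresholdReport:
    thresholds: np.ndarray
    accuracy: np.ndarray
    precision: np.ndarray  # NaN where undefined (no positive predictions)
    cubic_fit: np.ndarray  # np.polyfit coefficients, highest degree first
    knee: float
    knee_at_boundary: bool
    intersection: float | None

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "accuracy": self.accuracy.tolist(),
            "precision": [None if np.isnan(p) else p for p in self.precision],
            "cubic_fit": self.cubic_fit.tolist(),
            "knee": self.knee,
            "knee_at_boundary": self.knee_at_boundary,
            "intersection": self.intersection,
        }


def confusion_counts(sim: np.ndarray, ref: np.ndarray, threshold: float):
    """TP/FP/TN/FN of sim-vs-ref binarization over unordered off-diagonal
    pairs; ref edges are the ground truth."""
    n = sim.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    pred = sim[iu, ju] >= threshold
    truth = ref[iu, ju] >= threshold
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return tp, fp, tn, fn


def select_binarization_threshold(
    sim: np.ndarray, ref: np.ndarray, n_thresholds: int = 100
) -> ThresholdReport:
    """Sweep absolute thresholds in [0, 1], score the simulated FC against
    the reference FC as a binary edge classifier, and locate two candidate
    operating points: the knee of a cubic fit to precision, and the
    accuracy/precision crossing.

    Accuracy = (TP+TN)/all pairs; precision = TP/(TP+FP), undefined (and
    excluded from the cubic fit) where nothing is predicted positive.  The
    knee maximizes the curvature |y''| / (1 + y'^2)^(3/2) of the fitted
    cubic; the intersection is the root of interpolated accuracy minus
    fitted precision, ties broken toward the smaller threshold.
    """
    sim = np.asarray(sim, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if sim.shape != ref.shape:
        raise ValueError("sim and ref must share a shape")
    if n_thresholds < 3:
        raise ValueError("need at least 3 thresholds")
    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    accuracy = np.empty(n_thresholds)
    precision = np.full(n_thresholds, np.nan)
    for k, t in enumerate(thresholds):
        tp, fp, tn, fn = confusion_counts(sim, ref, t)
        total = tp + fp + tn + fn
        accuracy[k] = (tp + tn) / total if total else np.nan
        if tp + fp > 0:
            precision[k] = tp / (tp + fp)

    valid = ~np.isnan(precision)
    if valid.sum() < 4:
        raise ValueError("too few thresholds with defined precision for a cubic fit")
    coeffs = np.polyfit(thresholds[valid], precision[valid], deg=3)
    p = np.poly1d(coeffs)
    dp, d2p = p.deriv(1), p.deriv(2)
    lo, hi = thresholds[valid][0], thresholds[valid][-1]
    grid = np.linspace(lo, hi, 2001)
    curvature = np.abs(d2p(grid)) / (1.0 + dp(grid) ** 2) ** 1.5
    k_idx = int(np.argmax(curvature))
    knee = float(grid[k_idx])
    knee_at_boundary = k_idx in (0, grid.size - 1)

    # accuracy (linear interpolation) minus fitted precision, first root
    diff = np.interp(grid, thresholds, accuracy) - p(grid)
    intersection = None
    sign = np.sign(diff)
    for k in range(grid.size - 1):
        if sign[k] == 0:
            intersection = float(grid[k])
            break
        if sign[k] * sign[k + 1] < 0:
            x0, x1 = grid[k], grid[k + 1]
            y0, y1 = diff[k], diff[k + 1]
            intersection = float(x0 - y0 * (x1 - x0) / (y1 - y0))
            break
    return ThresholdReport(
        thresholds, accuracy, precision, coeffs, knee, knee_at_boundary, intersection
    )
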