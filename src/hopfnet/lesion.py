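"""In silico perturbation suite.

A lesion shifts one region's bifurcation parameter into the noise-driven
regime (a = -2) while everything else — connectome, remaining parameters,
and by default the noise realization — is held fixed.  The suite derives:

* a PerturbationEnsemble: baseline + one single-node lesion per region,
  each summarized by static FC, phase metrics and the dynamic-FC
  similarity distribution;
* robustness curves: relative giant-component size of the binarized FC
  after lesioning an increasing fraction of regions, at random or in
  decreasing structural hub-score order;
* nodal and inter-system (link) vulnerability maps from relative FC
  changes, split into hyper- (increase) and hypo- (decrease) connectivity;
* a hazard map: distance of each lesioned brain from the healthy baseline
  in a 13-d static feature space (null-normalized global efficiency,
  per-system local efficiency and segregation) plus a 3-d phase feature
  space (dFC KS coordinate, synchrony, metastability);
* correlations of hazard with structural centralities, FDR-corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectome import StructuralConnectome, structural_centralities, unity_normalize
from .dynamics import (
    ModelParameters,
    SimulationConfig,
    apply_perturbation,
    extract_bold,
    simulate,
)
from .fitting import summarize_signals
from .graphtools import (
    giant_component_fraction,
    local_efficiency,
    normalize_by_null,
    system_segregation,
    threshold_binarize,
)
from .graphtools import global_efficiency as binary_global_efficiency
from .observables import SimilarityDistribution, StaticFC, ks_distance

__all__ = [
    "LesionSummary",
    "PerturbationEnsemble",
    "VulnerabilityMaps",
    "HazardMap",
    "RobustnessCurve",
    "run_perturbation_suite",
    "robustness_curves",
    "nodal_vulnerability",
    "link_vulnerability",
    "hazard_map",
    "hazard_centrality_association",
]

A_LESION_DEFAULT = -2.0


@dataclass
class LesionSummary:
    fc: StaticFC
    modularity: float
    dfc: SimilarityDistribution
    synchrony: float
    metastability: float
    mean_amplitude: np.ndarray  # time-mean |z| per node


@dataclass
class PerturbationEnsemble:
    baseline: LesionSummary
    lesions: list[LesionSummary]  # indexed by lesioned node
    a_lesion: float
    seed: int
    labels: list[str]
    partition: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.lesions)


@dataclass
class VulnerabilityMaps:
    nodal_hyper: np.ndarray
    nodal_hypo: np.ndarray
    link_hyper: pd.DataFrame | None = None
    link_hypo: pd.DataFrame | None = None


@dataclass
class HazardMap:
    static_distance: np.ndarray
    phase_distance: np.ndarray
    hazard: np.ndarray
    labels: list[str]
    static_features: np.ndarray | None = None  # (N+1) x 13, unity-normalized


@dataclass
class RobustnessCurve:
    f_grid: np.ndarray
    fraction_in_giant: np.ndarray
    strategy: str
    threshold: float
    n_rep: int


def _summarize(signals, traj_z, partition, max_pairs, seed) -> LesionSummary:
    fc, q, dfc, coh = summarize_signals(
        signals, partition, max_pairs=max_pairs, seed=seed
    )
    return LesionSummary(
        fc=fc,
        modularity=q,
        dfc=dfc,
        synchrony=coh.synchrony,
        metastability=coh.metastability,
        mean_amplitude=np.abs(traj_z).mean(axis=0),
    )


def run_perturbation_suite(
    c: StructuralConnectome,
    p_opt: ModelParameters,
    cfg: SimulationConfig,
    partition=None,
    a_lesion: float = A_LESION_DEFAULT,
    max_pairs: int | None = 50_000,
    independent_seeds: bool = False,
) -> PerturbationEnsemble:
    """One baseline simulation plus one simulation per single-node lesion.

    By default every lesion reuses the baseline's noise seed so that
    differences are attributable to the lesion rather than to the noise
    realization; ``independent_seeds`` draws a fresh seed per lesion.
    """
    partition = partition if partition is not None else c.partition
    if partition is None:
        raise ValueError("a node partition is required")
    p_opt = p_opt.broadcast(c.n_nodes)
    if not np.all(p_opt.a > 0):
        raise ValueError("baseline must be oscillatory (a > 0 everywhere)")

    def run(params: ModelParameters, seed: int) -> LesionSummary:
        cfg_k = SimulationConfig(
            dt=cfg.dt, duration=cfg.duration, burn_in=cfg.burn_in, tr=cfg.tr,
            seed=seed, record_frequencies=False,
        )
        traj = simulate(c, params, cfg_k)
        return _summarize(extract_bold(traj), traj.z, partition, max_pairs, cfg.seed)

    baseline = run(p_opt, cfg.seed)
    lesions = []
    for node in range(c.n_nodes):
        seed = cfg.seed if not independent_seeds else cfg.seed + 1 + node
        try:
            lesions.append(run(apply_perturbation(p_opt, [node], a_lesion), seed))
        except Exception as exc:  # annotate with the target node
            raise RuntimeError(f"lesion simulation failed for node {node}") from exc
    return PerturbationEnsemble(
        baseline, lesions, a_lesion, cfg.seed, list(c.labels), list(partition)
    )


def robustness_curves(
    c: StructuralConnectome,
    p_opt: ModelParameters,
    cfg: SimulationConfig,
    strategy: str = "random",
    f_grid=np.linspace(0.0, 0.8, 9),
    threshold: float = 0.08,
    n_rep: int = 100,
    seed: int = 0,
    a_lesion: float = A_LESION_DEFAULT,
) -> RobustnessCurve:
    """Giant-component size of the binarized simulated FC after lesioning a
    fraction f of regions, relative to the unlesioned giant component.

    ``strategy`` is "random" (n_rep seeded node draws per f, averaged) or
    "targeted" (descending structural hub score).
    """
    if strategy not in ("random", "targeted"):
        raise ValueError("strategy must be 'random' or 'targeted'")
    if strategy == "random" and n_rep < 1:
        raise ValueError("n_rep must be >= 1 for the random strategy")
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any((f_grid < 0) | (f_grid > 1)):
        raise ValueError("f_grid values must lie in [0, 1]")
    p_opt = p_opt.broadcast(c.n_nodes)
    n = c.n_nodes
    rng = np.random.default_rng(seed)

    def giant_after(targets) -> float:
        params = apply_perturbation(p_opt, targets, a_lesion)
        from .observables import static_fc

        traj = simulate(c, params, cfg)
        fc = static_fc(extract_bold(traj))
        return giant_component_fraction(threshold_binarize(fc.values, threshold))

    baseline_giant = giant_after([])
    hub_order = None
    if strategy == "targeted":
        ct = structural_centralities(c)
        hub_order = np.argsort(-ct["hub_score"].to_numpy(), kind="stable")

    values = np.empty(f_grid.size)
    for k, f in enumerate(f_grid):
        n_lesion = int(np.floor(f * n))
        if n_lesion == 0:
            values[k] = 1.0
            continue
        if strategy == "targeted":
            values[k] = giant_after(hub_order[:n_lesion]) / baseline_giant
        else:
            reps = [
                giant_after(rng.choice(n, size=n_lesion, replace=False))
                for _ in range(n_rep)
            ]
            values[k] = float(np.mean(reps)) / baseline_giant
    # a lesioned run can reconnect nodes the baseline giant missed; the
    # relative size is capped at 1 so the curve stays a survival fraction
    values = np.minimum(values, 1.0)
    return RobustnessCurve(f_grid, values, strategy, threshold, n_rep)


def nodal_vulnerability(e: PerturbationEnsemble) -> VulnerabilityMaps:
    """Per-node means of positive (hyper) and negative (hypo) relative
    changes in FC nodal strength across lesion scenarios."""
    base = e.baseline.fc.nodal_strength()
    if np.any(base == 0):
        raise ValueError("zero baseline nodal strength")
    rel = np.stack(
        [(les.fc.nodal_strength() - base) / base for les in e.lesions]
    )  # scenario x node
    pos = np.where(rel > 0, rel, np.nan)
    neg = np.where(rel < 0, rel, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        hyper = np.nan_to_num(np.nanmean(pos, axis=0), nan=0.0)
        hypo = np.nan_to_num(np.nanmean(neg, axis=0), nan=0.0)
    return VulnerabilityMaps(nodal_hyper=hyper, nodal_hypo=hypo)


def _inter_system_fc(fc: StaticFC, part: np.ndarray, systems: list[str]) -> np.ndarray:
    s = len(systems)
    out = np.full((s, s), np.nan)
    for i in range(s):
        for j in range(i + 1, s):
            a = np.flatnonzero(part == systems[i])
            b = np.flatnonzero(part == systems[j])
            out[i, j] = out[j, i] = fc.values[np.ix_(a, b)].mean()
    return out


def link_vulnerability(e: PerturbationEnsemble, partition=None) -> VulnerabilityMaps:
    """Inter-system FC divergence maps: mean positive (hyper) and negative
    (hypo) relative changes of between-system mean FC across scenarios."""
    part = np.asarray(
        [str(p) for p in (partition if partition is not None else e.partition)]
    )
    systems = list(dict.fromkeys(part))
    if len(systems) < 2:
        raise ValueError("need at least 2 systems")
    base = _inter_system_fc(e.baseline.fc, part, systems)
    divs = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for les in e.lesions:
            lm = _inter_system_fc(les.fc, part, systems)
            divs.append((lm - base) / base)
    divs = np.stack(divs)
    divs[:, np.isclose(base, 0.0)] = np.nan  # undefined where baseline is 0
    pos = np.where(divs > 0, divs, np.nan)
    neg = np.where(divs < 0, divs, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        hyper = np.nanmean(pos, axis=0)
        hypo = np.nanmean(neg, axis=0)
    offdiag = ~np.eye(len(systems), dtype=bool)
    hyper[offdiag & np.isnan(hyper)] = 0.0
    hypo[offdiag & np.isnan(hypo)] = 0.0
    vm = VulnerabilityMaps(
        nodal_hyper=np.zeros(0),
        nodal_hypo=np.zeros(0),
        link_hyper=pd.DataFrame(hyper, index=systems, columns=systems),
        link_hypo=pd.DataFrame(hypo, index=systems, columns=systems),
    )
    return vm


def _static_feature_vector(
    summary: LesionSummary, part: np.ndarray, systems: list[str],
    threshold: float, n_null: int, null_seed: int,
) -> np.ndarray:
    g = threshold_binarize(summary.fc.values, threshold)
    feats = [
        normalize_by_null(g, "global_efficiency", n_null=n_null, seed=null_seed)
    ]
    for s in systems:
        nodes = np.flatnonzero(part == s)
        feats.append(
            normalize_by_null(
                g, "local_efficiency", n_null=n_null, seed=null_seed,
                system_nodes=nodes,
            )
        )
    seg = system_segregation(summary.fc.values, part)
    feats.extend(seg[s] for s in systems)
    return np.asarray(feats, dtype=float)


def hazard_map(
    e: PerturbationEnsemble,
    partition=None,
    threshold: float = 0.08,
    n_null: int = 20,
    null_seed: int = 0,
) -> HazardMap:
    """Feature-space hazardousness of each lesion target.

    Static features per set (baseline + N lesions): null-normalized global
    efficiency, per-system null-normalized local efficiency, per-system
    segregation — 13 features with 6 systems — each unity-normalized across
    the N+1 sets; static_distance is each lesion's Euclidean distance from
    baseline.  Phase features: dFC KS distance to the baseline distribution
    (entering as the coordinate difference directly), plus unity-normalized
    synchrony and metastability.  Both distances are unity-normalized
    across the N lesions and summed into the hazard score in [0, 2].
    Missing (undefined) features are imputed with the across-set median.
    """
    part = np.asarray(
        [str(p) for p in (partition if partition is not None else e.partition)]
    )
    systems = list(dict.fromkeys(part))
    sets = [e.baseline, *e.lesions]
    feats = np.stack(
        [
            _static_feature_vector(s, part, systems, threshold, n_null, null_seed)
            for s in sets
        ]
    )  # (N+1) x (1 + 2S)
    # impute undefined features (e.g., nonpositive within-system FC) with medians
    for j in range(feats.shape[1]):
        col = feats[:, j]
        if np.isnan(col).any():
            col[np.isnan(col)] = np.nanmedian(col)
    feats_n = np.stack([unity_normalize(feats[:, j]) for j in range(feats.shape[1])], axis=1)
    static_dist = np.linalg.norm(feats_n[1:] - feats_n[0], axis=1)

    sync = unity_normalize(np.array([s.synchrony for s in sets]))
    meta = unity_normalize(np.array([s.metastability for s in sets]))
    ks = np.array([ks_distance(s.dfc, e.baseline.dfc) for s in sets])
    phase_dist = np.sqrt(
        (sync[1:] - sync[0]) ** 2 + (meta[1:] - meta[0]) ** 2 + ks[1:] ** 2
    )
    hazard = unity_normalize(static_dist) + unity_normalize(phase_dist)
    return HazardMap(static_dist, phase_dist, hazard, list(e.labels), feats_n)


def hazard_centrality_association(
    h: HazardMap, centralities: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of the hazard score with clustering, degree,
    strength and local efficiency; two-sided p-values with
    Benjamini-Hochberg correction across the four tests."""
    hz = np.asarray(h.hazard, dtype=float)
    if hz.std() == 0:
        raise ValueError("constant hazard vector")
    measures = ["clustering", "degree", "strength", "local_efficiency"]
    rows = []
    for mname in measures:
        r, p = stats.pearsonr(hz, centralities[mname].to_numpy())
        rows.append((mname, r, p))
    df = pd.DataFrame(rows, columns=["measure", "r", "p"]).set_index("measure")
    reject, p_adj, *_ = multipletests(df["p"].to_numpy(), alpha=alpha, method="fdr_bh")
    df["p_fdr"] = p_adj
    df["significant"] = reject
    return df
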