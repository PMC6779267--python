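"""Signal-level summaries: static FC, modularity, instantaneous phases,
phase-coherence dynamic FC, the Kuramoto order parameter, and
intrinsic-frequency estimation.

Static FC is the Pearson correlation matrix of the regional signals.
Instantaneous phases come from the analytic (Hilbert) signal, with the
FOUR-quadrant arctangent; pairwise instantaneous coherence is
1 - |sin(delta theta)|; the dynamic-FC summary is the distribution of
cosine similarities between half-vectorized instantaneous FC matrices at
distinct time points, compared between runs by the two-sample
Kolmogorov-Smirnov statistic.  The order parameter r(t) = |mean_j
exp(i theta_j)| yields synchrony (time mean) and metastability (time SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy import stats

from .dynamics import RegionalSignals

__all__ = [
    "StaticFC",
    "PhaseSeries",
    "SimilarityDistribution",
    "CoherenceSeries",
    "static_fc",
    "group_average_fc",
    "fc_similarity",
    "modularity",
    "hilbert_phases",
    "instantaneous_fc",
    "dfc_similarity_distribution",
    "ks_distance",
    "order_parameter",
    "estimate_intrinsic_frequencies",
]


@dataclass
class StaticFC:
    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC must be square")
        self.values = v
        if self.labels is None:
            self.labels = [str(i) for i in range(v.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu, ju]

    def nodal_strength(self) -> np.ndarray:
        """Signed row sums excluding the diagonal."""
        return self.values.sum(axis=1) - np.diag(self.values)


@dataclass
class PhaseSeries:
    phases: np.ndarray  # time x node, wrapped to (-pi, pi]
    tr: float

    @property
    def n_times(self) -> int:
        return self.phases.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.phases.shape[1]


@dataclass
class SimilarityDistribution:
    samples: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float).ravel()
        if s.size == 0:
            raise ValueError("empty similarity distribution")
        self.samples = s

    def ecdf(self, x: np.ndarray) -> np.ndarray:
        srt = np.sort(self.samples)
        return np.searchsorted(srt, x, side="right") / srt.size


@dataclass
class CoherenceSeries:
    r: np.ndarray
    phi: np.ndarray
    synchrony: float
    metastability: float


def bandpass_filter(
    s: RegionalSignals, band: tuple[float, float] = (0.02, 0.12), order: int = 4
) -> RegionalSignals:
    """Zero-phase Butterworth band-pass of the regional signals, for parity
    experiments against band-limited reference data (simulated signals are
    not filtered by default)."""
    low, high = band
    nyq = 0.5 / s.tr
    if not 0 < low < high < nyq:
        raise ValueError("band must lie within (0, Nyquist)")
    sos = sp_signal.butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    return RegionalSignals(
        sp_signal.sosfiltfilt(sos, s.data, axis=0), tr=s.tr, labels=s.labels
    )


def static_fc(s: RegionalSignals) -> StaticFC:
    """Pairwise Pearson correlation matrix of the regional signals."""
    x = s.data
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points for correlations")
    degenerate = x.std(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    if degenerate.any():
        warnings.warn("constant signal column(s); correlations set to 0")
        r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return StaticFC(r, s.labels)


def group_average_fc(fcs: list[StaticFC]) -> StaticFC:
    """Fisher-z average of subject FC matrices; diagonal forced to 1."""
    if not fcs:
        raise ValueError("empty FC collection")
    n = fcs[0].n_nodes
    zsum = np.zeros((n, n))
    for fc in fcs:
        if fc.n_nodes != n:
            raise ValueError("FC matrices must share a shape")
        v = np.clip(fc.values, -1 + 1e-7, 1 - 1e-7)
        zsum += np.arctanh(v)
    out = np.tanh(zsum / len(fcs))
    np.fill_diagonal(out, 1.0)
    return StaticFC(out, fcs[0].labels)


def fc_similarity(a: StaticFC, b: StaticFC) -> float:
    """Pearson correlation between the strict upper triangles of two FC
    matrices."""
    x, y = a.upper_triangle(), b.upper_triangle()
    if x.shape != y.shape:
        raise ValueError("FC matrices must share a shape")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (constant) FC triangle")
    return float(np.corrcoef(x, y)[0, 1])


def modularity(fc: StaticFC | np.ndarray, partition) -> float:
    """Newman modularity Q of the FC matrix under a fixed partition.

    Q = (1/v) sum_{ij} (w_ij - s_i s_j / v) delta(c_i, c_j), over all
    ordered pairs including i = j with w_ii := 0.  Negative FC weights are
    clipped to zero first (the measure is defined for positive weights).
    """
    w = fc.values.copy() if isinstance(fc, StaticFC) else np.asarray(fc, dtype=float).copy()
    w = np.clip(w, 0.0, None)
    np.fill_diagonal(w, 0.0)
    part = np.asarray([str(p) for p in partition])
    if part.size != w.shape[0]:
        raise ValueError("partition must cover every node")
    v = w.sum()
    if v == 0:
        raise ValueError("total weight is zero")
    s = w.sum(axis=1)
    same = part[:, None] == part[None, :]
    q = ((w - np.outer(s, s) / v) * same).sum() / v
    return float(q)


def hilbert_phases(s: RegionalSignals, trim_fraction: float = 0.05) -> PhaseSeries:
    """Instantaneous phases of the demeaned analytic signal (four-quadrant
    arctangent).  The first and last ``trim_fraction`` of time points are
    discarded to suppress Hilbert edge effects."""
    x = s.data
    if x.shape[0] < 8:
        raise ValueError("need at least 8 time points")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("constant signal column")
    analytic = sp_signal.hilbert(x - x.mean(axis=0), axis=0)
    phases = np.angle(analytic)
    n_trim = int(np.floor(trim_fraction * x.shape[0]))
    if n_trim > 0:
        phases = phases[n_trim:-n_trim]
    return PhaseSeries(phases, s.tr)


def phases_from_model(z: np.ndarray, tr: float) -> PhaseSeries:
    """Four-quadrant phases taken directly from the complex model state
    (alternative to the analytic-signal route)."""
    return PhaseSeries(np.angle(z), tr)


def instantaneous_fc(p: PhaseSeries, t: int) -> np.ndarray:
    """Phase-coherence matrix 1 - |sin(theta_i - theta_j)| at time t."""
    theta = p.phases[t]
    d = theta[:, None] - theta[None, :]
    return 1.0 - np.abs(np.sin(d))


def _instantaneous_fc_vectors(p: PhaseSeries) -> np.ndarray:
    """Strict-upper-triangle vectors of every instantaneous FC matrix,
    stacked time x pair."""
    theta = p.phases
    iu, ju = np.triu_indices(p.n_nodes, k=1)
    d = theta[:, iu] - theta[:, ju]
    return 1.0 - np.abs(np.sin(d))


def dfc_similarity_distribution(
    p: PhaseSeries, max_pairs: int | None = 250_000, seed: int = 0
) -> SimilarityDistribution:
    """Distribution of cosine similarities between the half-vectorized
    instantaneous FC matrices of every unordered pair of distinct time
    points (or a seeded uniform subsample of ``max_pairs`` of them)."""
    if p.n_times < 2:
        raise ValueError("need at least 2 time points")
    vecs = _instantaneous_fc_vectors(p)
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm instantaneous FC vector")
    unit = vecs / norms[:, None]
    t = p.n_times
    n_all = t * (t - 1) // 2
    if max_pairs is None or n_all <= max_pairs:
        sim = unit @ unit.T
        iu, ju = np.triu_indices(t, k=1)
        samples = sim[iu, ju]
    else:
        rng = np.random.default_rng(seed)
        flat = rng.choice(n_all, size=max_pairs, replace=False)
        # map flat upper-triangle index -> (i, j)
        iu, ju = np.triu_indices(t, k=1)
        i_sel, j_sel = iu[flat], ju[flat]
        samples = np.einsum("kp,kp->k", unit[i_sel], unit[j_sel])
    return SimilarityDistribution(np.clip(samples, -1.0, 1.0))


def ks_distance(a: SimilarityDistribution, b: SimilarityDistribution) -> float:
    """Two-sample Kolmogorov-Smirnov statistic between the two similarity
    distributions."""
    return float(stats.ks_2samp(a.samples, b.samples, method="asymp").statistic)


def order_parameter(p: PhaseSeries) -> CoherenceSeries:
    """Kuramoto order parameter r(t), its ensemble phase, and the derived
    synchrony (time mean of r) and metastability (time SD of r)."""
    field = np.exp(1j * p.phases).mean(axis=1)
    r = np.abs(field)
    phi = np.angle(field)
    return CoherenceSeries(r, phi, float(r.mean()), float(r.std()))


def welch_peak_frequency(
    x: np.ndarray, fs: float, band: tuple[float, float], nperseg: int | None = None
) -> float:
    """In-band frequency of maximal Welch power-spectral density (Hz)."""
    t = x.shape[0]
    if nperseg is None:
        nperseg = min(256, t // 2)
    freqs, psd = sp_signal.welch(x, fs=fs, nperseg=nperseg, axis=0)
    low, high = band
    sel = (freqs >= low) & (freqs <= high)
    if not sel.any():
        raise ValueError("frequency band is empty after discretization")
    return freqs[sel][np.argmax(psd[sel], axis=0)]


def estimate_intrinsic_frequencies(
    subject_signals: list[RegionalSignals], band: tuple[float, float] = (0.02, 0.12)
) -> np.ndarray:
    """Per-node intrinsic angular frequency (rad/s): in-band Welch spectral
    peak per subject and node, median across subjects, times 2*pi."""
    if not subject_signals:
        raise ValueError("need at least one subject")
    low, high = band
    nyquist = 0.5 / subject_signals[0].tr
    if not 0 < low < high < nyquist:
        raise ValueError("band must lie within (0, Nyquist)")
    peaks = []
    for s in subject_signals:
        fs = 1.0 / s.tr
        peaks.append(welch_peak_frequency(s.data, fs, band))
    return 2.0 * np.pi * np.median(np.stack(peaks, axis=0), axis=0)
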