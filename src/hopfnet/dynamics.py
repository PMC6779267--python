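"""Adaptive frequency-modulated Stuart-Landau whole-brain dynamics.

Each region j carries a complex state z_j = r e^{i theta} near a Hopf
bifurcation, coupled diffusively through the structural connectome C, and a
free-running angular frequency omega_j relaxing toward its intrinsic drive
while being modulated by the net phase of its structural neighbourhood:

    dz_j/dt     = (a_j + i omega_j - |z_j|^2) z_j
                  + G * sum_i C_ij (z_i - z_j) + beta eta_j
    domega_j/dt = omega0_j - lambda omega_j + m psi_j,
    psi_j       = sum_i C_ij theta_i,   theta_i = atan(Im z_i / Re z_i)

with theta the TWO-quadrant arctangent on [-pi/2, pi/2] (a deliberate model
convention, distinct from the four-quadrant phase used on signals) and
eta_j independent complex white noise.  For a_j > 0 the uncoupled noise-free
region settles on a limit cycle of radius sqrt(a_j); for a_j < 0 it decays
to a noise-driven fixed point.  With m = 0 the system reduces to classic
coupled Stuart-Landau oscillators running at omega0/lambda after relaxation.

Integration is Euler-Maruyama with additive noise of per-step standard
deviation beta*sqrt(dt) in each of the real and imaginary components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .connectome import StructuralConnectome

__all__ = [
    "ModelParameters",
    "SimulationConfig",
    "TrajectorySet",
    "RegionalSignals",
    "simulate",
    "extract_bold",
    "apply_perturbation",
    "two_quadrant_phase",
]


@dataclass
class ModelParameters:
    """Parameters of the adaptive oscillator model.

    a and omega0 are per-node (scalars broadcast); G, lam, m, beta are
    global.  omega0 and lam are in rad/s and 1/s; a, G, m dimensionless;
    beta in signal units.
    """

    a: np.ndarray | float
    omega0: np.ndarray | float
    G: float
    lam: float
    m: float
    beta: float = 0.02

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.omega0 = np.atleast_1d(np.asarray(self.omega0, dtype=float))
        for name in ("G", "lam", "m", "beta"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, v)
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.lam <= 0 and (self.m != 0 or np.any(self.omega0 != 0)):
            raise ValueError("lam must be positive when frequency dynamics are active")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.omega0))):
            raise ValueError("a and omega0 must be finite")

    def broadcast(self, n_nodes: int) -> "ModelParameters":
        a = np.broadcast_to(self.a, (n_nodes,)).copy() if self.a.size in (1, n_nodes) else None
        w = (
            np.broadcast_to(self.omega0, (n_nodes,)).copy()
            if self.omega0.size in (1, n_nodes)
            else None
        )
        if a is None or w is None:
            raise ValueError("per-node parameter length does not match connectome size")
        return ModelParameters(a, w, self.G, self.lam, self.m, self.beta)


@dataclass
class SimulationConfig:
    dt: float = 0.01
    duration: float = 60.0 + 1190 * 0.72
    burn_in: float = 60.0
    tr: float = 0.72
    seed: int = 0
    record_frequencies: bool = True
    record_psi: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.dt <= self.tr:
            raise ValueError("need 0 < dt <= tr")
        if self.burn_in >= self.duration:
            raise ValueError("burn_in must be smaller than duration")
        if self.n_samples < 2:
            raise ValueError("config yields fewer than 2 output samples")

    @property
    def steps_per_sample(self) -> int:
        return max(1, int(round(self.tr / self.dt)))

    @property
    def n_samples(self) -> int:
        usable = self.duration - self.burn_in
        return int(np.floor(usable / (self.steps_per_sample * self.dt))) + 1


@dataclass
class TrajectorySet:
    times: np.ndarray
    z: np.ndarray  # complex, time x node
    omega: np.ndarray | None = None
    psi: np.ndarray | None = None
    tr: float = 0.72
    labels: list[str] | None = None


@dataclass
class RegionalSignals:
    """Real-valued time x node signal matrix sampled every ``tr`` seconds."""

    data: np.ndarray
    tr: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ValueError("data must be 2-D (time x node)")
        if d.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if not np.all(np.isfinite(d)):
            raise ValueError("signals must be finite")
        self.data = d
        if self.labels is None:
            self.labels = [str(i) for i in range(d.shape[1])]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[0]


def two_quadrant_phase(z: np.ndarray) -> np.ndarray:
    """atan(Im z / Re z) on [-pi/2, pi/2]; Re z = 0 maps to sign(Im z)*pi/2
    and z = 0 maps to 0."""
    re, im = np.real(z), np.imag(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.arctan(np.divide(im, re, out=np.zeros_like(im), where=re != 0))
    theta = np.where(re == 0, np.sign(im) * (np.pi / 2), theta)
    return theta


class SimulationBlowupError(RuntimeError):
    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite state at integration step {step}")


try:  # optional jitted integrator; the numpy loop below is the reference
    from numba import njit as _njit

    @_njit(cache=True)
    def _integrate_jit(C, row_sum, a, omega0, G, lam, m, beta, zre, zim, w, dt,
                       n_burn, spp, n_samples, rng):
        n = zre.shape[0]
        sqrt_dt = np.sqrt(dt)
        total_steps = n_burn + (n_samples - 1) * spp
        zs = np.empty((n_samples, n), dtype=np.complex128)
        ws = np.empty((n_samples, n))
        noisy = beta > 0
        sample_idx = 0
        half_pi = np.pi / 2
        theta = np.empty(n)
        for step in range(total_steps + 1):
            if step >= n_burn and (step - n_burn) % spp == 0:
                for j in range(n):
                    if not (np.isfinite(zre[j]) and np.isfinite(zim[j])):
                        return zs, ws, step
                    zs[sample_idx, j] = complex(zre[j], zim[j])
                    ws[sample_idx, j] = w[j]
                sample_idx += 1
            if step == total_steps:
                break
            for j in range(n):
                if zre[j] == 0.0:
                    theta[j] = np.sign(zim[j]) * half_pi
                else:
                    theta[j] = np.arctan(zim[j] / zre[j])
            psi = C @ theta
            c_re = C @ zre
            c_im = C @ zim
            for j in range(n):
                # (a + i w - |z|^2) z + G (Cz - s z)
                r2 = zre[j] * zre[j] + zim[j] * zim[j]
                dre = (a[j] - r2) * zre[j] - w[j] * zim[j] + G * (c_re[j] - row_sum[j] * zre[j])
                dim = (a[j] - r2) * zim[j] + w[j] * zre[j] + G * (c_im[j] - row_sum[j] * zim[j])
                zre[j] = zre[j] + dt * dre
                zim[j] = zim[j] + dt * dim
            if noisy:
                nre = rng.standard_normal(n)
                nim = rng.standard_normal(n)
                for j in range(n):
                    zre[j] = zre[j] + beta * nre[j] * sqrt_dt
                    zim[j] = zim[j] + beta * nim[j] * sqrt_dt
            for j in range(n):
                w[j] = w[j] + dt * (omega0[j] - lam * w[j] + m * psi[j])
        return zs, ws, -1

except ImportError:  # pragma: no cover - numba is an optional accelerator
    _integrate_jit = None


def _initial_state(
    rng: np.random.Generator, a: np.ndarray, omega0: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    n = a.size
    radius = np.maximum(np.sqrt(np.maximum(a, 0.0)), 0.1)
    r = radius * np.sqrt(rng.random(n))
    phi = rng.uniform(-np.pi, np.pi, size=n)
    z0 = r * np.exp(1j * phi)
    w0 = omega0 / lam if lam > 0 else omega0.copy()
    return z0, w0


def simulate(
    c: StructuralConnectome, p: ModelParameters, cfg: SimulationConfig
) -> TrajectorySet:
    """Integrate the coupled system by Euler-Maruyama and record states
    every ``cfg.tr`` seconds after discarding ``cfg.burn_in``.

    Deterministic for a fixed ``cfg.seed``.  Raises SimulationBlowupError
    with the offending step index if the state leaves the finite range.
    """
    n = c.n_nodes
    p = p.broadcast(n)
    C = c.weights
    row_sum = C.sum(axis=1)
    rng = np.random.default_rng(cfg.seed)
    z, w = _initial_state(rng, p.a, p.omega0, p.lam)

    if _integrate_jit is not None and not cfg.record_psi:
        zs, ws, bad_step = _integrate_jit(
            C, row_sum, p.a, p.omega0, p.G, p.lam, p.m, p.beta,
            np.real(z).copy(), np.imag(z).copy(), w.astype(float), cfg.dt,
            int(round(cfg.burn_in / cfg.dt)), cfg.steps_per_sample,
            cfg.n_samples, rng,
        )
        if bad_step >= 0:
            raise SimulationBlowupError(int(bad_step))
        times = cfg.burn_in + np.arange(cfg.n_samples) * cfg.steps_per_sample * cfg.dt
        return TrajectorySet(
            times, zs, ws if cfg.record_frequencies else None, None,
            tr=cfg.steps_per_sample * cfg.dt, labels=list(c.labels),
        )

    dt = cfg.dt
    sqrt_dt = np.sqrt(dt)
    spp = cfg.steps_per_sample
    n_burn = int(round(cfg.burn_in / dt))
    n_samples = cfg.n_samples
    total_steps = n_burn + (n_samples - 1) * spp

    zs = np.empty((n_samples, n), dtype=complex)
    ws = np.empty((n_samples, n)) if cfg.record_frequencies else None
    psis = np.empty((n_samples, n)) if cfg.record_psi else None

    a, omega0, G, lam, m, beta = p.a, p.omega0, p.G, p.lam, p.m, p.beta
    noisy = beta > 0
    sample_idx = 0

    def record(k: int) -> None:
        zs[k] = z
        if ws is not None:
            ws[k] = w
        if psis is not None:
            psis[k] = C @ two_quadrant_phase(z)

    for step in range(total_steps + 1):
        if step >= n_burn and (step - n_burn) % spp == 0:
            record(sample_idx)
            sample_idx += 1
        if step == total_steps:
            break
        theta = two_quadrant_phase(z)
        psi = C @ theta
        coupling = G * (C @ z - row_sum * z)
        dz = (a + 1j * w - np.abs(z) ** 2) * z + coupling
        z = z + dt * dz
        if noisy:
            z = z + beta * (rng.standard_normal(n) + 1j * rng.standard_normal(n)) * sqrt_dt
        w = w + dt * (omega0 - lam * w + m * psi)
        if step % 200 == 0 and not (np.all(np.isfinite(z.view(float))) and np.all(np.isfinite(w))):
            raise SimulationBlowupError(step)

    if not (np.all(np.isfinite(zs.view(float))) and (ws is None or np.all(np.isfinite(ws)))):
        raise SimulationBlowupError(total_steps)

    times = cfg.burn_in + np.arange(n_samples) * spp * dt
    return TrajectorySet(times, zs, ws, psis, tr=spp * dt, labels=list(c.labels))


def extract_bold(t: TrajectorySet) -> RegionalSignals:
    """BOLD-like observable: the real part of z at the recorded instants."""
    if t.z.size == 0:
        raise ValueError("empty trajectory")
    return RegionalSignals(np.real(t.z), tr=t.tr, labels=t.labels)


def apply_perturbation(
    p: ModelParameters, targets, a_lesion: float = -2.0, n_nodes: int | None = None
) -> ModelParameters:
    """Lesioned parameter copy: targeted nodes get bifurcation parameter
    ``a_lesion`` (default -2, the noise-driven regime); everything else is
    untouched."""
    targets = sorted(int(t) for t in np.atleast_1d(np.asarray(targets, dtype=int)).ravel()) if np.size(targets) else []
    if n_nodes is None:
        n_nodes = max(p.a.size, p.omega0.size)
    q = p.broadcast(n_nodes)
    for t in targets:
        if not 0 <= t < n_nodes:
            raise IndexError(f"lesion target {t} out of range for {n_nodes} nodes")
        q.a[t] = a_lesion
    return q
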