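"""File formats and run configuration.

Connectome and FC matrices travel as tab-delimited text with a first row of
region labels; partitions as two-column (region, system) tab-delimited
text; trajectories as HDF5 or tab-delimited time x region text; metric
summaries and manifests as JSON; run configuration as YAML.  Matrix writers
use repr-precision floats so write-then-read is bit-exact.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import yaml

from .connectome import StructuralConnectome
from .dynamics import RegionalSignals, SimulationConfig, TrajectorySet

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_partition",
    "read_signals",
    "write_signals",
    "write_trajectory_h5",
    "read_trajectory_h5",
    "load_config",
    "write_manifest",
]


class MatrixParseError(ValueError):
    pass


def write_matrix(path, values: np.ndarray, labels) -> None:
    values = np.asarray(values, dtype=float)
    labels = [str(x) for x in labels]
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        for row in values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a labelled square matrix; symmetrize sub-1e-9 asymmetry with a
    warning, reject anything worse."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise MatrixParseError(f"{path}: empty file")
    labels = lines[0].split("\t")
    n = len(labels)
    if len(lines) - 1 != n:
        raise MatrixParseError(
            f"{path}: expected {n} data rows for {n} labels, found {len(lines) - 1}"
        )
    rows = []
    for k, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != n:
            raise MatrixParseError(f"{path}: line {k} has {len(cells)} cells, expected {n}")
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise MatrixParseError(f"{path}: line {k}: non-numeric cell ({exc})") from exc
    m = np.asarray(rows)
    asym = np.abs(m - m.T).max()
    if asym > 1e-9:
        raise MatrixParseError(f"{path}: matrix asymmetry {asym:g} exceeds 1e-9")
    if asym > 0:
        warnings.warn(f"{path}: asymmetry {asym:g} within tolerance; symmetrized")
        m = 0.5 * (m + m.T)
    return m, labels


def read_connectome(matrix_path, partition_path=None) -> StructuralConnectome:
    w, labels = read_matrix(matrix_path)
    partition = None
    if partition_path is not None:
        pmap = read_partition(partition_path)
        partition = [pmap[lab] for lab in labels]
    return StructuralConnectome(w, labels, partition)


def write_partition(path, labels, partition) -> None:
    with open(path, "w") as fh:
        for lab, sys_ in zip(labels, partition):
            fh.write(f"{lab}\t{sys_}\n")


def read_partition(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for k, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise MatrixParseError(f"{path}: line {k}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def write_signals(path, s: RegionalSignals) -> None:
    write_matrix_like_timeseries(path, s.data, s.labels, s.tr)


def write_matrix_like_timeseries(path, data, labels, tr) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tr={tr!r}\n")
        fh.write("\t".join(str(x) for x in labels) + "\n")
        for row in np.asarray(data, dtype=float):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_signals(path) -> RegionalSignals:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# tr="):
            raise MatrixParseError(f"{path}: missing '# tr=' header")
        tr = float(first.strip().split("=", 1)[1])
        labels = fh.readline().rstrip("\n").split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.shape[1] != len(labels):
        raise MatrixParseError(f"{path}: column count does not match labels")
    return RegionalSignals(data, tr=tr, labels=labels)


def write_trajectory_h5(path, t: TrajectorySet) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=t.times)
        fh.create_dataset("z_real", data=np.real(t.z))
        fh.create_dataset("z_imag", data=np.imag(t.z))
        if t.omega is not None:
            fh.create_dataset("omega", data=t.omega)
        if t.psi is not None:
            fh.create_dataset("psi", data=t.psi)
        fh.attrs["tr"] = t.tr
        if t.labels is not None:
            fh.attrs["labels"] = json.dumps(list(t.labels))


def read_trajectory_h5(path) -> TrajectorySet:
    with h5py.File(path, "r") as fh:
        z = fh["z_real"][()] + 1j * fh["z_imag"][()]
        omega = fh["omega"][()] if "omega" in fh else None
        psi = fh["psi"][()] if "psi" in fh else None
        labels = json.loads(fh.attrs["labels"]) if "labels" in fh.attrs else None
        return TrajectorySet(fh["times"][()], z, omega, psi, float(fh.attrs["tr"]), labels)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    return SimulationConfig(
        dt=float(d.get("dt", 0.01)),
        duration=float(d.get("duration", 60.0 + 1190 * 0.72)),
        burn_in=float(d.get("burn_in", 60.0)),
        tr=float(d.get("tr", 0.72)),
        seed=int(d.get("seed", 0)),
        record_frequencies=bool(d.get("record_frequencies", True)),
    )


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seed: int, input_paths: dict) -> Path:
    """Machine-readable run manifest: config, master seed, input digests,
    package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": _digest(p)}
            for name, p in input_paths.items()
            if p is not None and Path(p).exists()
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
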