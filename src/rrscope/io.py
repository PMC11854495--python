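"""Readers/writers and experiment orchestration.

File conventions: CSV is comma-separated, '.' decimal, UTF-8, with a
mandatory header row in outputs.  Weight matrices travel as TSV with a
JSON sidecar recording the generating condition and seed; trajectories
as CSV with a leading step column.  Recorded voltage series are
two-column delimited text (time in seconds, potential in mV) with an
optional header, or single-column values with an explicit sampling
interval.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .info import SweepResult, detect_rr, noise_sweep
from .network import (ConditionSpec, Trajectory, WeightMatrix, condition,
                      sample_weights, simulate)
from .spectral import (fit_slope, low_half_band, neuron_trace_spectrum,
                       spectral_noise_default)

__all__ = [
    "read_timeseries",
    "write_weights",
    "read_weights",
    "write_trajectory",
    "read_trajectory",
    "write_sweep",
    "RunConfig",
    "run_experiment",
]


def read_timeseries(path, dt: float | None = None) -> tuple[np.ndarray, float]:
    """Load a recorded series; returns (values_mV, dt_seconds).

    Two-column files carry their own time axis, which must be uniform:
    any successive step deviating from the median dt by more than 1%
    raises an error naming the offending sample index.  Single-column
    files require an explicit ``dt``.
    """
    path = Path(path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            parts = ln.replace("\t", ",").replace(";", ",").split(",")
            try:
                rows.append([float(p) for p in parts if p != ""])
            except ValueError:
                if rows:
                    raise
                continue  # header line
    if not rows:
        raise ValueError(f"{path}: no numeric data found")
    arr = np.asarray(rows, dtype=float)
    if arr.shape[1] == 1:
        if dt is None:
            raise ValueError(f"{path}: single-column file requires an explicit dt")
        return arr[:, 0], float(dt)
    t, v = arr[:, 0], arr[:, 1]
    steps = np.diff(t)
    med = float(np.median(steps))
    if med <= 0:
        raise ValueError(f"{path}: non-increasing time axis")
    bad = np.flatnonzero(np.abs(steps - med) > 0.01 * med)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"{path}: non-uniform sampling at index {i + 1} "
            f"(t={t[i]}->{t[i + 1]}, step {steps[i]:.6g} vs median {med:.6g})")
    return v, med


def write_weights(weights: WeightMatrix, path) -> None:
    """TSV matrix plus a .json sidecar with condition provenance."""
    path = Path(path)
    np.savetxt(path, weights.entries, delimiter="\t", fmt="%.17g")
    spec = weights.condition
    meta = {
        "seed": weights.seed,
        "n_total": weights.n_total,
        "condition": None if spec is None else {
            "name": spec.name,
            "topology": spec.topology,
            "n": spec.n,
            "class_ranges": {k: list(v) for k, v in spec.class_ranges.items()},
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2), encoding="utf-8")


def read_weights(path) -> WeightMatrix:
    path = Path(path)
    entries = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    meta_path = path.with_suffix(path.suffix + ".json")
    spec = None
    seed = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        seed = meta.get("seed")
    return WeightMatrix(entries=entries, condition=spec, seed=seed)


def write_trajectory(traj, path, binary: bool = False) -> None:
    data = traj.bits if binary else traj.states
    n = data.shape[1]
    df = pd.DataFrame(data, columns=[f"s{i}" for i in range(n)])
    df.insert(0, "step", np.arange(len(df)))
    df.to_csv(path, index=False)


def read_trajectory(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.drop(columns=["step"]).to_numpy()


def write_sweep(sweep: SweepResult, path) -> None:
    """Tidy CSV plus a .json metadata sidecar embedding the config hash."""
    path = Path(path)
    sweep.to_csv(path)
    meta = {
        "condition": sweep.condition,
        "scope": sweep.scope,
        "subset": None if sweep.subset is None else list(sweep.subset),
        "T": sweep.T,
        "weight_strengths": list(sweep.weight_strengths),
        "noise_grid": list(sweep.noise_grid),
        "base_seed": sweep.base_seed,
        "seeds": sorted(set(int(s) for s in sweep.table["seed"])),
    }
    meta["config_sha256"] = hashlib.sha256(
        json.dumps(meta, sort_keys=True).encode()).hexdigest()
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2), encoding="utf-8")


@dataclass
class RunConfig:
    """Validated description of a full sweep -> detection -> spectrum run."""

    condition: str = "diagonal"
    topology: str = "linear"
    n: int = 5
    weight_strengths: tuple = (1.0, 2.0, 5.0, 10.0)
    noise_grid: tuple = tuple(np.round(np.arange(0.1, 5.001, 0.1), 10))
    T: int = 10_000
    scope: str | tuple = "global"
    seed: int = 0
    n_reps: int = 1
    spectral: bool = False
    spectral_trials: int = 50
    spectral_T: int = 8192
    spectral_W: float = 2.0
    neuron: int = 0
    theta: float | None = None
    out_dir: str = "."

    def spec(self) -> ConditionSpec:
        return condition(self.condition, self.topology, self.n)

    def validate(self) -> None:
        if self.T < 2 or self.spectral_T < 8:
            raise ValueError("T too small")
        if len(self.noise_grid) < 3:
            raise ValueError("noise grid needs at least 3 points")
        self.spec()  # raises on bad condition/topology


def run_experiment(config: RunConfig) -> dict:
    """Sweep -> RR detection -> optional single-neuron spectrum.

    Writes sweep CSV (+ JSON sidecar with all seeds and the config
    hash) and, when requested, a spectrum CSV and a JSON report.  A
    rerun with an identical config is bit-identical.  Returns the paths
    and headline numbers.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.spec()

    sweep = noise_sweep(spec, config.weight_strengths, config.noise_grid,
                        config.T, scope=config.scope, seed=config.seed,
                        n_reps=config.n_reps)
    sweep_path = out / "sweep.csv"
    write_sweep(sweep, sweep_path)

    detections = {}
    for W in config.weight_strengths:
        det = detect_rr(sweep, W)
        detections[W] = dataclasses.asdict(det)

    result = {
        "sweep_csv": str(sweep_path),
        "detections": {str(W): d for W, d in detections.items()},
        "config": dataclasses.asdict(config),
    }

    if config.spectral:
        r_spec = spectral_noise_default(sweep, config.spectral_W)
        ps = neuron_trace_spectrum(spec, config.spectral_W, r_spec,
                                   config.spectral_T, config.spectral_trials,
                                   neuron=config.neuron, seed=config.seed)
        fit = fit_slope(ps, low_half_band(ps), n_log_bins=12)
        spec_path = out / "spectrum.csv"
        pd.DataFrame({"f": ps.frequencies, "S": ps.power}).to_csv(
            spec_path, index=False)
        result.update({
            "spectrum_csv": str(spec_path),
            "spectral_noise": r_spec,
            "low_band_slope": fit.slope,
            "low_band": list(fit.band),
        })

    report_path = out / "report.json"
    report_path.write_text(json.dumps(result, indent=2, default=float),
                           encoding="utf-8")
    result["report_json"] = str(report_path)
    return result
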