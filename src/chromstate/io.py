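"""Configuration parsing, trajectory TSV round-tripping and test fixtures."""

from __future__ import annotations

import json
import tomllib
from dataclasses import fields
from pathlib import Path

import numpy as np

from . import __version__
from .engine import (
    KNOB_NAMES,
    RateModifiers,
    SimulationConfig,
    Trajectory,
    apply_knob,
)

__all__ = [
    "ConfigError",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "write_manifest",
    "make_telegraph_fixture",
    "replication_sidecar_path",
    "manifest_path",
]


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration content."""


_CONFIG_FIELDS = {f.name for f in fields(SimulationConfig)} - {"multipliers"}
_MULTIPLIER_FIELDS = {f.name for f in fields(RateModifiers)}


def load_config(path: str | Path) -> SimulationConfig:
    """Load a simulation config from TOML (or JSON).

    Top-level keys are SimulationConfig field names or the eight enzyme
    knobs (trxg, utx, cbp, prc1, prc2, kdm, nurd, prdub); a ``multipliers``
    table may set the seven per-complex multipliers directly.  The ``nurd``
    knob sets both the direct deacetylation rate and the recruited
    NURD-compound multiplier.  Unknown keys are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    else:
        try:
            data = tomllib.loads(path.read_text())
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config root must be a table/object")
    return config_from_dict(data)


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    mult_table = data.pop("multipliers", {})
    unknown = set(data) - _CONFIG_FIELDS - set(KNOB_NAMES)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    bad_mult = set(mult_table) - _MULTIPLIER_FIELDS
    if bad_mult:
        raise ConfigError(f"unknown multiplier keys: {sorted(bad_mult)}")

    plain = {k: v for k, v in data.items() if k in _CONFIG_FIELDS}
    try:
        config = SimulationConfig(
            **plain, multipliers=RateModifiers(**mult_table)
        )
        for knob in KNOB_NAMES:
            if knob in data:
                config = apply_knob(config, knob, data[knob])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config value: {exc}") from exc
    return config


def replication_sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".replication.tsv")


def manifest_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".manifest.json")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as TSV: time, N half states, six category counts.

    Replication events go to a ``.replication.tsv`` sidecar and the config
    echo to a ``.manifest.json`` sidecar next to the main file.
    """
    path = Path(path)
    n = traj.n_halves
    header = (
        ["time"]
        + [f"h{i + 1}" for i in range(n)]
        + [f"cat{c}" for c in range(1, 7)]
    )
    cats = traj.category_counts()
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for k in range(traj.n_samples):
            row = [f"{traj.times[k]:.6g}"]
            row += [str(int(s)) for s in traj.states[k]]
            row += [str(int(c)) for c in cats[k]]
            fh.write("\t".join(row) + "\n")
    with replication_sidecar_path(path).open("w") as fh:
        fh.write("time\n")
        for t in traj.replication_times:
            fh.write(f"{t:.6g}\n")
    write_manifest(traj, manifest_path(path))


def write_manifest(traj: Trajectory, path: str | Path) -> None:
    manifest = {
        "version": __version__,
        "config": traj.config.to_dict(),
        "seed": traj.config.seed,
        "start_time": float(traj.times[0]) if traj.n_samples else None,
        "end_time": float(traj.times[-1]) if traj.n_samples else None,
        "n_samples": traj.n_samples,
        "stats": traj.stats,
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    times: list[float] = []
    states: list[list[int]] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "time":
            raise ValueError(f"{path}: unexpected header {header!r}")
        n = sum(1 for c in header if c.startswith("h") and c[1:].isdigit())
        expected_cols = 1 + n + 6
        if len(header) != expected_cols:
            raise ValueError(
                f"{path}: header has {len(header)} columns, expected {expected_cols}"
            )
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != expected_cols:
                raise ValueError(
                    f"{path}:{lineno}: {len(parts)} columns, expected {expected_cols}"
                )
            try:
                times.append(float(parts[0]))
                states.append([int(p) for p in parts[1 : 1 + n]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc

    rep_file = replication_sidecar_path(path)
    rep_times: list[float] = []
    if rep_file.exists():
        with rep_file.open() as fh:
            fh.readline()
            rep_times = [float(line) for line in fh if line.strip()]

    man_file = manifest_path(path)
    if man_file.exists():
        config = SimulationConfig.from_dict(json.loads(man_file.read_text())["config"])
    else:
        t = times if len(times) > 1 else [0.0, 1.0]
        config = SimulationConfig(
            n=max(n, 2),
            duration=times[-1] if times else 0.0,
            sample_interval=max(t[1] - t[0], 1e-9),
        )
    return Trajectory(
        times=np.asarray(times, dtype=np.float64),
        states=np.asarray(states, dtype=np.int8),
        replication_times=np.asarray(rep_times, dtype=np.float64),
        config=config,
    )


def make_telegraph_fixture(
    epoch_lengths,
    states_per_epoch,
    sample_interval: float = 1.0,
    n: int = 20,
) -> Trajectory:
    """Synthetic trajectory alternating between fixed array compositions.

    ``states_per_epoch`` gives, per epoch, the (first, second) half-state
    pair applied to every whole nucleosome for that epoch.  Used as an
    oracle for the regime classifier.
    """
    if len(epoch_lengths) != len(states_per_epoch):
        raise ValueError("epoch_lengths and states_per_epoch must align")
    if any(length <= 0 for length in epoch_lengths):
        raise ValueError("epoch lengths must be > 0")
    times: list[float] = []
    rows: list[np.ndarray] = []
    t = 0.0
    boundary = 0.0
    for length, (i, j) in zip(epoch_lengths, states_per_epoch):
        row = np.empty(n, dtype=np.int8)
        row[0::2] = i
        row[1::2] = j
        boundary += length
        while t < boundary - 1e-12:
            times.append(t)
            rows.append(row)
            t += sample_interval
    duration = float(sum(epoch_lengths))
    config = SimulationConfig(
        n=n, duration=duration, sample_interval=sample_interval
    )
    return Trajectory(
        times=np.asarray(times),
        states=np.vstack(rows),
        replication_times=np.empty(0),
        config=config,
    )
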