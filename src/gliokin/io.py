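"""Delimited-text serialization for trajectories, observation series,
result tables and fit results.

Dialect is fixed to avoid locale drift: comma-separated, "." decimal
point, no thousands separators, UTF-8, LF line endings. Floats are
written with 12 significant digits, and readers round-trip values
bit-identically at that precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitResult, ObservationSeries
from .simulate import Trajectory

__all__ = ["write_table", "read_table", "write_trajectory",
           "read_trajectory", "write_series", "read_series",
           "write_fit_result", "write_manifest", "sha256_digest"]

_FLOAT_FMT = "%.12g"
_SERIES_MAGIC = "# gliokin-series "

TRAJECTORY_COLUMNS = ("time_hr", "igfi_free_nM", "igfbp2_nM", "complex_nM",
                      "hif1a_uM", "gd_um", "volume_um3")


def write_table(df: pd.DataFrame, path) -> None:
    """CSV with the fixed dialect and 12-significant-digit floats."""
    df.to_csv(path, index=False, float_format=_FLOAT_FMT,
              lineterminator="\n", encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def write_trajectory(traj: Trajectory, path) -> None:
    write_table(traj.to_frame(), path)


def read_trajectory(path) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"trajectory file {os.fspath(path)!r} is missing column(s): "
            f"{', '.join(missing)}")
    return df


def write_series(series: ObservationSeries, path) -> None:
    """Series CSV with a one-line JSON metadata header comment."""
    meta = {
        "observable": series.observable,
        "weight": series.weight,
        "env_overrides": series.env_overrides,
        "metadata": series.metadata,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_SERIES_MAGIC + json.dumps(meta, sort_keys=True) + "\n")
        fh.write("coordinate,value\n")
        for c, v in zip(series.coords, series.values):
            fh.write(f"{c:.12g},{v:.12g}\n")


def read_series(path) -> ObservationSeries:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith(_SERIES_MAGIC):
            raise ValueError(
                f"{os.fspath(path)!r} is not an observation-series file "
                "(missing metadata header)")
        meta = json.loads(first[len(_SERIES_MAGIC):])
        df = pd.read_csv(fh)
    return ObservationSeries(
        observable=meta["observable"],
        coords=df["coordinate"].to_numpy(dtype=float),
        values=df["value"].to_numpy(dtype=float),
        weight=float(meta.get("weight", 1.0)),
        env_overrides=meta.get("env_overrides", {}),
        metadata=meta.get("metadata", {}),
    )


def write_fit_result(result: FitResult, path) -> None:
    """FitResult as JSON including seed and full config for replay."""
    payload = {
        "params": result.params.as_dict(),
        "free_params": list(result.free_params),
        "objective_value": result.objective_value,
        "ga_best_objective": result.ga_best_objective,
        "per_series": result.per_series,
        "ga_config": dataclasses.asdict(result.ga_config),
        "seed": result.seed,
        "bounds": {k: list(v) for k, v in result.bounds.items()},
        "convergence": result.convergence,
        "n_evaluations": result.n_evaluations,
        "package_version": __version__,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, config: dict,
                   outputs: list, seed: int | None = None) -> str:
    """JSON run manifest: command, config snapshot, seed, package
    version, output digests and a UTC timestamp."""
    manifest = {
        "command": command,
        "config": _jsonable(config),
        "seed": seed,
        "package_version": __version__,
        "outputs": {
            os.path.basename(os.fspath(p)): sha256_digest(p)
            for p in outputs
        },
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = os.path.join(os.fspath(out_dir), "manifest.json")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
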