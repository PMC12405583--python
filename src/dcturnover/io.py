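"""CSV / JSON / YAML readers and writers.

All tables are UTF-8 CSV with a header row and "." decimals; nested results
go to JSON.  Reports embed provenance (package version, seed, a hash of the
resolved configuration) so every number is regenerable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, InvalidInputError
from .spatial import ClusterAssignment, PointPattern
from .timecourse import LabelTimeCourse

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "read_points",
    "write_points",
    "write_cluster_csv",
    "load_yaml_config",
    "write_report",
]


def read_timecourse(path) -> LabelTimeCourse:
    """Read the ``timecourse.csv`` schema: columns ``time``, ``unit``
    (days|hours), ``replicate``, ``population``, ``percent_labelled``."""
    df = pd.read_csv(path, float_precision="round_trip")
    try:
        return LabelTimeCourse.from_dataframe(df)
    except InvalidInputError as exc:
        raise InvalidInputError(f"{path}: {exc}") from exc


def write_timecourse(tc: LabelTimeCourse, path) -> None:
    # %.17g guarantees bit-exact float round trips through the CSV
    tc.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_points(path) -> PointPattern:
    """Read ``points.csv``: columns ``x_um``, ``y_um`` and optional ``marker``."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"x_um", "y_um"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {sorted(missing)}")
    marker = df["marker"].to_numpy() if "marker" in df.columns else None
    return PointPattern(df[["x_um", "y_um"]].to_numpy(dtype=float), marker)


def write_points(pattern: PointPattern, path) -> None:
    df = pd.DataFrame(
        {"x_um": pattern.coordinates[:, 0], "y_um": pattern.coordinates[:, 1]}
    )
    if pattern.marker is not None:
        df["marker"] = pattern.marker
    df.to_csv(path, index=False, float_format="%.17g")


def write_cluster_csv(
    pattern: PointPattern, assignment: ClusterAssignment, path
) -> None:
    df = pd.DataFrame(
        {
            "x_um": pattern.coordinates[:, 0],
            "y_um": pattern.coordinates[:, 1],
            "cluster_id": assignment.labels,
            "cluster_size": assignment.size_of(np.arange(len(pattern))),
        }
    )
    if pattern.marker is not None:
        df["marker"] = pattern.marker
    df.to_csv(path, index=False)


def load_yaml_config(path, allowed_keys=None) -> dict:
    """Load a YAML mapping, rejecting unknown keys when a vocabulary is given."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - set(allowed_keys)
        if unknown:
            raise ConfigError(
                f"{path}: unknown config key(s) {sorted(unknown)}; "
                f"allowed: {sorted(allowed_keys)}"
            )
    return cfg


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def write_report(results: dict, path, seed=None, config: dict | None = None) -> None:
    """Write a JSON report with provenance (version, seed, config hash)."""
    from . import __version__

    payload = _jsonable(results)
    cfg = _jsonable(config or {})
    provenance = {
        "package": "dcturnover",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"provenance": provenance, "results": payload}, fh, indent=2)
        fh.write("\n")
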