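"""Recording/feature CSV dialects, manifests and configuration.

Recording CSV dialect: header ``time_s,<sensor1>,...,<sensorS>``, one row
per sample, decimal volts with 6 decimals (round-trip precision 5e-7 V),
UTF-8, LF line endings. Dataset manifests and PCA models are JSON.
Configuration is a flat YAML key/value file with a closed schema: unknown
keys are errors, not warnings, so a typo cannot silently change a run.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .core import AromaMeasurement
from .exceptions import ConfigError, ParseError

__all__ = [
    "read_recording",
    "write_recording",
    "write_manifest",
    "read_manifest",
    "DEFAULT_CONFIG",
    "load_config",
    "config_hash",
]

_VOLT_FMT = "%.6f"


def write_recording(m: AromaMeasurement, path: str | Path) -> None:
    """Serialize a recording in the CSV dialect (6-decimal volts, LF)."""
    path = Path(path)
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["time_s", *m.sensor_names])
        for t, row in zip(m.timestamps_s, m.voltages):
            w.writerow([_VOLT_FMT % t] + [_VOLT_FMT % v for v in row])


def read_recording(path: str | Path, label: str = "unknown") -> AromaMeasurement:
    """Parse a recording CSV; malformed input raises ParseError with the line."""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file", line=1) from None
        if len(header) < 2 or header[0] != "time_s":
            raise ParseError(
                f"expected header 'time_s,<sensor>,...', got {','.join(header)!r}",
                line=1,
            )
        sensor_names = tuple(header[1:])
        times: list[float] = []
        rows: list[list[float]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, got {len(rec)}", line=lineno
                )
            try:
                vals = [float(x) for x in rec]
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from None
            if times and vals[0] <= times[-1]:
                raise ParseError(
                    f"time {vals[0]} not greater than previous {times[-1]}",
                    line=lineno,
                )
            times.append(vals[0])
            rows.append(vals[1:])
    if not rows:
        raise ParseError("no data rows", line=2)
    return AromaMeasurement(
        timestamps_s=np.array(times),
        voltages=np.array(rows),
        sensor_names=sensor_names,
        label=label,
        metadata={"source": str(path)},
    )


def write_manifest(records: Sequence[dict], path: str | Path, extra: dict | None = None) -> None:
    """Write a dataset manifest (file path, label, seed, metadata) as JSON."""
    paths = [r["file"] for r in records]
    if len(set(paths)) != len(paths):
        raise ConfigError("duplicate file paths in manifest")
    for r in records:
        if not r.get("label"):
            raise ConfigError(f"record {r.get('file')!r} has an empty label")
    payload = {"records": list(records)}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_manifest(path: str | Path) -> dict:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid manifest JSON: {exc}") from None
    if "records" not in payload:
        raise ParseError("manifest missing 'records'")
    return payload


#: Closed configuration schema with defaults; values are overridable from
#: a flat YAML file and per-command CLI flags.
DEFAULT_CONFIG: dict[str, Any] = {
    "schema_version": 1,
    "duration_s": 2000.0,
    "sample_rate_hz": 1.0,
    "window_start_s": 500.0,
    "window_end_s": 1500.0,
    "relative_humidity": 0.0,
    "k_subdivisions": 8,
    "n_per_class": 20,
    "image_size": 128,
    "block_size": 100,
    "train_fraction": 0.8,
    "seed": 0,
    "backends": ["decision_tree", "random_forest", "xgboost", "svm"],
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Resolve configuration: defaults < YAML file < explicit overrides.

    Unknown keys at either level raise :class:`ConfigError` listing the
    valid keys.
    """
    cfg = dict(DEFAULT_CONFIG)
    for source_name, source in (
        ("config file", _read_yaml(path) if path else {}),
        ("overrides", overrides or {}),
    ):
        for key, value in source.items():
            if value is None:
                continue
            if key not in DEFAULT_CONFIG:
                raise ConfigError(
                    f"unknown {source_name} key {key!r}; valid keys: "
                    + ", ".join(sorted(DEFAULT_CONFIG))
                )
            cfg[key] = value
    return cfg


def _read_yaml(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError("config file must be a flat key/value mapping")
    return data


def config_hash(cfg: dict) -> str:
    """Stable short hash identifying a resolved configuration."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
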