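"""Output-directory handling, run manifests and small parsing helpers."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ConfigError

SCHEMA_VERSION = 1


def parse_axis_spec(spec: str) -> tuple[str, np.ndarray]:
    """Parse ``name:start:stop:count`` into (name, values), e.g. ``A:0:1:201``."""
    parts = spec.split(":")
    if len(parts) != 4:
        raise ConfigError(f"axis spec must be name:start:stop:count, got {spec!r}")
    name, start, stop, count = parts
    try:
        values = np.linspace(float(start), float(stop), int(count))
    except ValueError as exc:
        raise ConfigError(f"bad axis spec {spec!r}: {exc}") from exc
    if len(values) < 1:
        raise ConfigError(f"axis spec {spec!r} yields an empty axis")
    return name, values


def parse_ladder_spec(spec: str) -> np.ndarray:
    """Parse ``start:stop:count`` or a comma-separated list of exposures."""
    try:
        if ":" in spec:
            start, stop, count = spec.split(":")
            return np.linspace(float(start), float(stop), int(count))
        return np.array([float(v) for v in spec.split(",")])
    except ValueError as exc:
        raise ConfigError(f"bad exposure spec {spec!r}: {exc}") from exc


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(outdir: str | Path, command: str, resolved: dict) -> Path:
    """Record the fully resolved run configuration as JSON.

    Re-running with the manifest's parameters reproduces byte-identical CSV
    outputs (all computations are deterministic).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "comres",
        "version": __version__,
        "schema_version": SCHEMA_VERSION,
        "command": command,
        "config": _jsonable(resolved),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
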