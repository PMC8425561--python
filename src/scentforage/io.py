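"""Configuration files and result serialization.

Configs are flat YAML (or JSON — a YAML subset) mappings of the
:class:`~scentforage.config.SimulationConfig` fields; absent fields take
their defaults, unknown fields are an error.  A finished run is written as
plain-text tables (events, per-flower and per-pollinator CSV) plus a JSON
manifest carrying the config snapshot, seed, software version and summary
metrics — enough to replay the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import PARAMETER_INTERVALS, SimulationConfig
from .engine import SimulationResult
from .metrics import summarize

__all__ = ["load_config", "save_config", "write_result", "read_result"]

SCHEMA_VERSION = 1

_FILES = {
    "events": "events.csv",
    "flowers": "flowers.csv",
    "pollinators": "pollinators.csv",
    "manifest": "manifest.json",
}


def load_config(path: str | Path, **overrides) -> SimulationConfig:
    """Load and validate a config file; keyword overrides win over the file.

    An empty file yields the full default config.  Unknown fields and
    out-of-range values raise ``ValueError`` naming the offender.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat mapping of config fields")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return SimulationConfig.from_dict(raw)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}{_range_hint(str(exc))}") from None


def _range_hint(message: str) -> str:
    for name, (lo, hi) in PARAMETER_INTERVALS.items():
        if message.startswith(name):
            return f" (valid interval: [{lo}, {hi}])"
    return ""


def save_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def write_result(result: SimulationResult, out_dir: str | Path) -> dict[str, str]:
    """Write a result directory (three CSVs + manifest); returns the inventory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.events.to_csv(out / _FILES["events"], index=False)
    result.per_flower.to_csv(out / _FILES["flowers"], index=False)
    result.per_pollinator.to_csv(out / _FILES["pollinators"], index=False)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "written_at": datetime.now(timezone.utc).isoformat(),
        "config": result.config.to_dict(),
        "seed": result.seed,
        "total_refill": result.total_refill,
        "summary": {k: _jsonable(v) for k, v in summarize(result).to_dict().items()},
        "files": dict(_FILES),
    }
    (out / _FILES["manifest"]).write_text(json.dumps(manifest, indent=2))
    return dict(_FILES)


def _jsonable(v: float) -> float | None:
    return None if pd.isna(v) else float(v)


def read_result(out_dir: str | Path) -> SimulationResult:
    """Re-load a result directory written by :func:`write_result`."""
    out = Path(out_dir)
    manifest = json.loads((out / _FILES["manifest"]).read_text())
    config = SimulationConfig.from_dict(manifest["config"])
    events = pd.read_csv(out / _FILES["events"])
    per_flower = pd.read_csv(out / _FILES["flowers"])
    per_pollinator = pd.read_csv(out / _FILES["pollinators"])
    return SimulationResult(
        config=config,
        seed=manifest["seed"],
        per_pollinator=per_pollinator,
        per_flower=per_flower,
        events=events,
        total_refill=manifest["total_refill"],
    )
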