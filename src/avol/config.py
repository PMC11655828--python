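"""YAML configuration for brain wiring and protocol runs.

One YAML document configures a whole run::

    schema: 1
    brain:
      seed: 0
      gate_threshold: 0.3
      expectancy: [1.0, 0.6, 0.4]
      area_params:
        BA46: {tonic_drive: 1.0, noise_sd: 0.0225}
    protocol:
      n_iterations: 12
      iteration_duration: 2500.0

Unknown keys are errors (this protects hand-transcribed parameter
tables from silent typos); every omitted key falls back to the
documented default of the corresponding dataclass.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .brain import BrainConfig, BrainModel, Projection
from .network import AreaParams, GainParams
from .protocol import ProtocolConfig

__all__ = ["SCHEMA_VERSION", "load_config", "dump_config", "config_to_dict",
           "projections_table"]

SCHEMA_VERSION = 1


def _check_keys(d: dict, cls, where: str) -> None:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}; "
                         f"allowed: {sorted(allowed)}")


def _area_params(d: dict, where: str) -> dict:
    """Validate an AreaParams override mapping (kept as a dict so
    build_brain can layer it over the per-area defaults)."""
    _check_keys(d, AreaParams, where)
    out = dict(d)
    for key in ("gain_exc", "gain_ff", "gain_fb"):
        if key in out and isinstance(out[key], dict):
            _check_keys(out[key], GainParams, f"{where}.{key}")
            out[key] = GainParams(**out[key])
    return out


def load_config(path: str | Path) -> tuple[BrainConfig, ProtocolConfig]:
    """Read a YAML run configuration; strict about unknown keys."""
    path = Path(path)
    with open(path) as f:
        doc = yaml.safe_load(f) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(doc) - {"schema", "brain", "protocol"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    version = doc.get("schema", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema version {version}")

    brain_d = dict(doc.get("brain") or {})
    _check_keys(brain_d, BrainConfig, "brain")
    if "area_params" in brain_d:
        brain_d["area_params"] = {
            name: _area_params(dict(v), f"brain.area_params.{name}")
            for name, v in brain_d["area_params"].items()
        }
    if "expectancy" in brain_d:
        brain_d["expectancy"] = tuple(brain_d["expectancy"])
    if "carrier_band" in brain_d:
        brain_d["carrier_band"] = tuple(brain_d["carrier_band"])
    if "projections" in brain_d:
        projs = []
        for i, p in enumerate(brain_d["projections"]):
            _check_keys(p, Projection, f"brain.projections[{i}]")
            projs.append(Projection(**p))
        brain_d["projections"] = projs
    brain = BrainConfig(**brain_d)

    proto_d = dict(doc.get("protocol") or {})
    _check_keys(proto_d, ProtocolConfig, "protocol")
    if "replay_band" in proto_d:
        proto_d["replay_band"] = tuple(proto_d["replay_band"])
    protocol = ProtocolConfig(**proto_d)
    return brain, protocol


def config_to_dict(brain: BrainConfig, protocol: ProtocolConfig) -> dict:
    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        return obj

    b = plain(brain)
    return {"schema": SCHEMA_VERSION, "brain": b, "protocol": plain(protocol)}


def projections_table(brain: BrainModel):
    """The wiring as a DataFrame (exportable as CSV for inspection)."""
    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(p) for p in brain.projections])


def dump_config(brain: BrainConfig, protocol: ProtocolConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config_to_dict(brain, protocol), f, sort_keys=False)
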