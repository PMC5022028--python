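"""Config parsing, validation, CSV writing and run manifests.

Configs are flat YAML key-value files (see ``docs/config_schema.md`` for
keys and units), split into ``parameters``, ``phenotype`` and ``scenario``
sections.  Every command writes RFC-4180-style CSV ('.' decimal, ','
delimiter, UTF-8, mandatory header) plus a JSON run manifest recording the
command, config paths, a stable parameter hash, seeds and the package
version.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .parameters import CellPhenotype, ExposureScenario, ModelParameters

__all__ = [
    "ConfigError",
    "load_config",
    "parameters_from_config",
    "phenotype_from_config",
    "scenario_from_config",
    "parse_grid",
    "parameter_hash",
    "write_csv",
    "write_manifest",
    "write_parameters",
]


class ConfigError(ValueError):
    """A config file failed validation; the message names the fields."""


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping: {path}")
    return data


def _build(cls, section: dict, section_name: str, required: tuple[str, ...] = ()):
    if not isinstance(section, dict):
        raise ConfigError(f"section '{section_name}' must be a mapping")
    field_names = {f.name for f in dataclasses.fields(cls)}
    problems = [
        f"{section_name}.{key}: unknown key" for key in section if key not in field_names
    ]
    problems += [
        f"{section_name}.{key}: missing required key"
        for key in required
        if key not in section
    ]
    if problems:
        raise ConfigError("; ".join(problems))
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"section '{section_name}': {exc}") from exc


def parameters_from_config(config: dict) -> ModelParameters:
    return _build(ModelParameters, config.get("parameters", {}), "parameters")


def phenotype_from_config(config: dict, required: tuple[str, ...] = ("genome_gbp",)) -> CellPhenotype:
    if "phenotype" not in config:
        raise ConfigError("missing required section 'phenotype'")
    return _build(CellPhenotype, config["phenotype"], "phenotype", required=required)


def scenario_from_config(config: dict, **overrides) -> ExposureScenario:
    section = dict(config.get("scenario", {}))
    section.pop("doses", None)  # dose grids are handled by the caller
    section.update(overrides)
    section.setdefault("dose", 0.0)
    return _build(ExposureScenario, section, "scenario")


def parse_grid(spec) -> list[float]:
    """Parse a ``start:stop:step`` string (inclusive of both endpoints) or
    pass through an explicit list of numbers."""
    if isinstance(spec, (list, tuple)):
        return [float(v) for v in spec]
    if isinstance(spec, (int, float)):
        return [float(spec)]
    parts = str(spec).split(":")
    if len(parts) != 3:
        raise ConfigError(
            f"grid must be 'start:stop:step' or a list of numbers; got {spec!r}"
        )
    try:
        start, stop, step = (float(p) for p in parts)
    except ValueError:
        raise ConfigError(f"non-numeric grid component in {spec!r}") from None
    if step <= 0 or stop < start:
        raise ConfigError(f"need start <= stop and step > 0 in {spec!r}")
    n = int(round((stop - start) / step))
    values = [start + k * step for k in range(n + 1)]
    if values[-1] < stop - 1e-9:  # make the grid endpoint-inclusive
        values.append(stop)
    return values


def parameter_hash(params: ModelParameters) -> str:
    """Stable short hash of a parameter set, invariant to field order."""
    payload = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")
    return path


def write_manifest(
    path: str | Path,
    command: str,
    params: ModelParameters,
    config_paths: list[str] | None = None,
    seeds: list[int] | None = None,
    extra: dict | None = None,
) -> Path:
    from . import __version__

    manifest = {
        "command": command,
        "config_paths": [str(p) for p in (config_paths or [])],
        "parameter_hash": parameter_hash(params),
        "seeds": seeds or [],
        "version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def write_parameters(params: ModelParameters, path: str | Path) -> Path:
    """Write a parameter set as a config readable by ``parameters_from_config``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"parameters": params.to_dict()}, fh, sort_keys=True)
    return path
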