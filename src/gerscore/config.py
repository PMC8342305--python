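"""Configuration file support: TOML or YAML mirroring the config dataclasses.

Sections ``[qc]``, ``[score]``, ``[ph]`` and ``[sim]`` map field-by-field
onto :class:`QcConfig`, :class:`ScoreConfig`, :class:`PhConfig` and
:class:`SimConfig`.  Unknown keys are rejected so typos fail loudly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path
from typing import Any, Dict, Optional, Union

import yaml

from .errors import ConfigurationError
from .ph_metry import COMPONENTS, PhConfig
from .scoring import ScoreConfig
from .spectral_qc import QcConfig
from .synthetic import SimConfig

__all__ = ["load_config_file", "make_configs", "config_hash"]

_SECTIONS = {"qc": QcConfig, "score": ScoreConfig, "ph": PhConfig, "sim": SimConfig}


def load_config_file(path: Union[str, Path]) -> Dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"{path}: no such config file")
    if path.suffix.lower() == ".toml":
        with path.open("rb") as fh:
            return tomllib.load(fh)
    if path.suffix.lower() in (".yaml", ".yml"):
        with path.open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return data or {}
    raise ConfigurationError(f"{path}: config must be .toml or .yaml")


def _build(section: str, cls, values: Dict[str, Any], overrides: Dict[str, Any]):
    merged = {**values, **overrides}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(merged) - names
    if unknown:
        raise ConfigurationError(f"[{section}] unknown keys: {sorted(unknown)}")
    if section == "ph" and "component_norms" in merged and merged["component_norms"] is not None:
        norms = merged["component_norms"]
        if isinstance(norms, str):
            from .ph_metry import identity_norms, placeholder_norms

            if norms == "identity":
                merged["component_norms"] = identity_norms()
            elif norms == "placeholder":
                merged["component_norms"] = placeholder_norms()
            else:
                raise ConfigurationError(
                    f"[ph] component_norms must be 'identity', 'placeholder' or a "
                    f"mapping of the six components {COMPONENTS}"
                )
        else:
            merged["component_norms"] = {
                k: (float(v[0]), float(v[1])) for k, v in dict(norms).items()
            }
    for tup in ("event_band", "artifact_band"):
        if tup in merged and merged[tup] is not None:
            merged[tup] = tuple(merged[tup])
    try:
        return cls(**merged)
    except TypeError as exc:
        raise ConfigurationError(f"[{section}] {exc}") from exc


def make_configs(
    file_data: Optional[Dict[str, Any]] = None,
    overrides: Optional[Dict[str, Dict[str, Any]]] = None,
) -> Dict[str, Any]:
    """Build all four config objects from file data plus per-section overrides.

    Precedence: dataclass defaults < config file < explicit overrides
    (CLI flags).
    """
    file_data = file_data or {}
    overrides = overrides or {}
    unknown = set(file_data) - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    return {
        name: _build(name, cls, file_data.get(name, {}), overrides.get(name, {}))
        for name, cls in _SECTIONS.items()
    }


def config_hash(configs: Dict[str, Any]) -> str:
    """Stable digest of the effective configuration (for run manifests)."""

    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    blob = json.dumps({k: enc(v) for k, v in sorted(configs.items())}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()
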