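"""YAML configuration for the generator and pipeline.

Diel and seasonal profiles are functions and therefore referenced by name
in YAML; the registry below maps names to implementations.
"""

from __future__ import annotations

import dataclasses

import yaml

from .errors import ConfigurationError
from .synthetic_data import (
    SyntheticConfig,
    default_diel_profile,
    default_season_trend,
)


def _flat(_x):
    import numpy as np

    return np.ones_like(np.asarray(_x, dtype=float))


def _zero(_x):
    import numpy as np

    return np.zeros_like(np.asarray(_x, dtype=float))


PROFILES = {
    "crepuscular": default_diel_profile,
    "hyperphagia": default_season_trend,
    "flat": _flat,
    "zero": _zero,
}

_FUNC_FIELDS = {"diel_profile": "crepuscular", "season_trend": "hyperphagia"}


def config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d or {})
    valid = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in _FUNC_FIELDS:
        if key in d and isinstance(d[key], str):
            if d[key] not in PROFILES:
                raise ConfigurationError(
                    f"{key}={d[key]!r} not in profiles {sorted(PROFILES)}")
            d[key] = PROFILES[d[key]]
    if "years" in d:
        d["years"] = tuple(int(y) for y in d["years"])
    return SyntheticConfig(**d)


def load_config(path) -> SyntheticConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return config_from_dict(payload.get("simulate", payload))


def default_config_dict() -> dict:
    out = {}
    for f in dataclasses.fields(SyntheticConfig):
        v = getattr(SyntheticConfig(), f.name)
        out[f.name] = _FUNC_FIELDS.get(f.name, v) if callable(v) else v
    out["years"] = list(out["years"])
    return out
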