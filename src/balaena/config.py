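"""Run configuration: defaults, YAML loading, strict validation."""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

#: every default matches the stated analysis protocol where one exists
DEFAULTS: dict[str, Any] = {
    "seed": 1,
    "focal_species": "mm_bmysticetus",
    "sister_species": "mm_balaenoptera",
    "reference_species": ["mm_btaurus", "mm_ttruncatus"],
    "stages": ["orthology", "qc", "selection", "residues", "expansion", "summary"],
    "orthology": {
        "evalue_cutoff": 1e-7,
        "min_species_exclusive": 7,
    },
    "qc": {
        "max_insert_bp": 12,
        "min_focal_fraction": 0.5,
        "min_pairwise_fraction": 0.5,
    },
    "selection": {
        "alpha": 0.05,
        "pp_threshold": 0.95,
        "start_omegas": [0.5, 1.0, 2.0],
        "site_dialect": "M1a",  # or "M1"
        "top_fraction": 0.05,
    },
    "residues": {
        "max_unknown_others": 1,
        "require_others_identical": False,
        "top_fraction": 0.05,
    },
    "expansion": {
        "min_diff_pct": 1.0,
        "max_diff_pct": 10.0,
        "min_reads": 10,
    },
    "summary": {
        "genome_size_gb": 2.91,
    },
}

_RANGES: dict[tuple[str, ...], tuple[float, float]] = {
    ("orthology", "evalue_cutoff"): (0.0, 10.0),
    ("orthology", "min_species_exclusive"): (1, 1000),
    ("qc", "max_insert_bp"): (0, 10_000),
    ("qc", "min_focal_fraction"): (0.0, 1.0),
    ("qc", "min_pairwise_fraction"): (0.0, 1.0),
    ("selection", "alpha"): (0.0, 1.0),
    ("selection", "pp_threshold"): (0.0, 1.0),
    ("selection", "top_fraction"): (0.0, 1.0),
    ("residues", "max_unknown_others"): (0, 100),
    ("residues", "top_fraction"): (0.0, 1.0),
    ("expansion", "min_diff_pct"): (0.0, 100.0),
    ("expansion", "max_diff_pct"): (0.0, 100.0),
    ("expansion", "min_reads"): (0, 10**9),
    ("summary", "genome_size_gb"): (1e-9, 1e6),
}


class ConfigError(ValueError):
    pass


def _merge(defaults: Mapping, overrides: Mapping, path: tuple = ()) -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in overrides.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key: {'.'.join(path + (key,))}")
        if isinstance(defaults[key], Mapping):
            if not isinstance(value, Mapping):
                raise ConfigError(
                    f"config key {'.'.join(path + (key,))} must be a mapping"
                )
            out[key] = _merge(defaults[key], value, path + (key,))
        else:
            out[key] = value
    return out


def validate(config: Mapping) -> dict:
    cfg = _merge(DEFAULTS, config)
    for (section, key), (lo, hi) in _RANGES.items():
        value = cfg[section][key]
        if not (lo <= value <= hi):
            raise ConfigError(
                f"{section}.{key}={value} outside allowed range [{lo}, {hi}]"
            )
    if cfg["expansion"]["min_diff_pct"] > cfg["expansion"]["max_diff_pct"]:
        raise ConfigError("expansion.min_diff_pct exceeds max_diff_pct")
    unknown_stages = set(cfg["stages"]) - set(DEFAULTS["stages"])
    if unknown_stages:
        raise ConfigError(f"unknown stages: {sorted(unknown_stages)}")
    if cfg["selection"]["site_dialect"] not in ("M1a", "M1"):
        raise ConfigError("selection.site_dialect must be M1a or M1")
    return cfg


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, overridden by the YAML file when given."""
    if path is None:
        return validate({})
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config file must contain a mapping")
    return validate(raw)
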