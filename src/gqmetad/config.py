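"""Run configuration: a flat, schema-validated YAML key tree.

Units are fixed globally (kcal/mol, Å, ps, K, rad) and never declared per
field.  Validation happens before any computation: unknown keys anywhere
in the tree are rejected, so a typo cannot silently fall back to a
default.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml

__all__ = ["ConfigError", "config_digest", "load_config", "validate_config"]


class ConfigError(ValueError):
    """Invalid run configuration; the message is a one-line cause."""


_SCHEMA = {
    "system": {
        "kind": str,
        # double well
        "barrier": (int, float),
        "separation": (int, float),
        "asymmetry": (int, float),
        "width": (int, float),
        # hopping landscape
        "plateau_height": (int, float),
        "barrier_ab_aa": (int, float),
        "offsets": {"Ab": (int, float), "B": (int, float)},
        # toy quadruplex
        "beads_per_strand": int,
        "rise": (int, float),
        "side": (int, float),
        "ligand_bond_length": (int, float),
    },
    "sampler": {
        "temperature": (int, float),
        "friction": (int, float),
        "timestep": (int, float),
        "mass": (int, float),
        "n_steps": int,
        "seed": int,
        "start": list,
        "record_stride": int,
    },
    "metad": {
        "delta_T": (int, float),
        "initial_height": (int, float),
        "pace": (int, float),
        "widths": list,
        "grid_bounds": list,
        "grid_bins": list,
        "bias_cvs": list,
    },
    "walls": list,
    "analysis": {
        "bound": list,
        "unbound": list,
        "bins": int,
        "depth_cutoff": (int, float),
        "reweight_cvs": list,
        "reweight_bins": int,
        "mode": str,
        "n_blocks": int,
    },
    "output": {"dir": str},
}

_WALL_KEYS = {"cv": str, "limit": (int, float), "spring": (int, float)}
_SYSTEM_KINDS = ("double_well", "hopping", "quadruplex")


def _check_section(name: str, section, schema) -> None:
    if not isinstance(section, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    for key, value in section.items():
        if key not in schema:
            raise ConfigError(f"unknown key {name}.{key}")
        expected = schema[key]
        if isinstance(expected, dict):
            _check_section(f"{name}.{key}", value, expected)
        elif not isinstance(value, expected):
            raise ConfigError(
                f"{name}.{key} has wrong type {type(value).__name__}")


def validate_config(cfg: dict, subcommand: str | None = None) -> dict:
    """Validate a configuration tree; returns it unchanged on success."""
    if not isinstance(cfg, dict):
        raise ConfigError("configuration root must be a mapping")
    for key, value in cfg.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown section {key!r}")
        if key == "walls":
            if not isinstance(value, list):
                raise ConfigError("walls must be a list")
            for i, w in enumerate(value):
                _check_section(f"walls[{i}]", w, _WALL_KEYS)
        else:
            _check_section(key, value, _SCHEMA[key])
    system = cfg.get("system", {})
    if "kind" in system and system["kind"] not in _SYSTEM_KINDS:
        raise ConfigError(f"system.kind must be one of {_SYSTEM_KINDS}")
    if subcommand in ("sample", "metad", "generate"):
        if "system" not in cfg or "kind" not in cfg["system"]:
            raise ConfigError(f"{subcommand} requires system.kind")
    if subcommand == "metad":
        metad = cfg.get("metad", {})
        if "grid_bounds" not in metad:
            raise ConfigError("metad requires metad.grid_bounds (the bias "
                              "grid must cover the walled domain)")
        if "widths" not in metad:
            raise ConfigError("metad requires metad.widths")
    return cfg


def load_config(path, subcommand: str | None = None) -> dict:
    try:
        cfg = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from None
    return validate_config(cfg or {}, subcommand)


def config_digest(cfg: dict) -> str:
    """Stable short digest of a configuration tree."""
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
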