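"""Run configuration, YAML round-tripping and validation-run presets.

Presets mirror the published validation protocol:

==========  =============================================================
run1        default window (3.65-5.57 A), default E_min
run2, run3  run1 with coordination filters >= 3 / >= 4 (selection only)
run4        strict distance window 4.13-5.09 A (mu +/- 1 sigma)
run5        energy cut-off E_min = -4 kcal/mol
run5.1      energy cut-off E_min = -5 kcal/mol
run6        water building disabled
run6.1      posterior solvation after packing
ligand      run5-like with chi1 +/- 10 deg rotamer expansion
==========  =============================================================

The default E_min of -2 kcal/mol for runs 1-3 is a package choice (the
protocol does not print one).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .chemistry import GeometryParams
from .energy import HBondParams

__all__ = ["RunConfig", "ConfigurationError", "resolve_preset",
           "load_config", "dump_config", "PRESETS"]


class ConfigurationError(ValueError):
    pass


@dataclass
class RunConfig:
    mode: str = "rebuild"        # rebuild|posterior|analyze|evaluate|fixture
    preset: str | None = None
    strict_window: bool = False
    build_waters: bool = True
    posterior: bool = False
    expand_chi1: bool = False
    min_coordination: int = 2
    seed: int = 0
    allow_water_partners: bool = False
    geometry: GeometryParams = field(default_factory=GeometryParams)
    energy: HBondParams = field(default_factory=HBondParams)


PRESETS = {
    "run1": {},
    "run2": {"min_coordination": 3},
    "run3": {"min_coordination": 4},
    "run4": {"strict_window": True},
    "run5": {"energy": {"accept_threshold": -4.0}},
    "run5.1": {"energy": {"accept_threshold": -5.0}},
    "run6": {"build_waters": False},
    "run6.1": {"posterior": True},
    "ligand": {"energy": {"accept_threshold": -4.0}, "expand_chi1": True},
}


def _apply(config: RunConfig, overrides: dict) -> RunConfig:
    known = {f.name for f in fields(RunConfig)}
    for key, value in overrides.items():
        if key not in known:
            raise ConfigurationError(f"unknown configuration key {key!r}")
        if key == "geometry":
            for k, v in value.items():
                if not hasattr(config.geometry, k):
                    raise ConfigurationError(
                        f"unknown geometry key {k!r}")
                setattr(config.geometry, k,
                        tuple(v) if isinstance(v, list) else v)
        elif key == "energy":
            for k, v in value.items():
                if not hasattr(config.energy, k):
                    raise ConfigurationError(f"unknown energy key {k!r}")
                setattr(config.energy, k,
                        tuple(v) if isinstance(v, list) else v)
        else:
            setattr(config, key, value)
    return config


def resolve_preset(name: str) -> RunConfig:
    """Fully specified configuration for a named validation preset."""
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; valid: {', '.join(sorted(PRESETS))}")
    config = RunConfig(preset=name)
    return _apply(config, PRESETS[name])


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    preset = data.pop("preset", None)
    config = resolve_preset(preset) if preset else RunConfig()
    return _apply(config, data)


def dump_config(config: RunConfig, path: str | None = None) -> str:
    text = yaml.safe_dump(asdict(config), sort_keys=False)
    if path:
        with open(path, "w") as fh:
            fh.write(text)
    return text
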