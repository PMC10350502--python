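"""Run configuration, presets and reproducible output writing.

Configuration files are flat YAML mappings (a strict subset: no nesting
beyond the documented keys); unknown keys are rejected so that typos
fail loudly.  Every run can write a provenance record (config hash,
package version, seed) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import yaml

from .model import LaserParams, PRESETS

__all__ = ["RunConfig", "load_config", "write_provenance", "dump_json"]

#: Floats are serialised at fixed significant digits to keep
#: cross-platform diffs stable.
FLOAT_DIGITS = 12


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.{FLOAT_DIGITS}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def dump_json(payload, path) -> None:
    """Write JSON with stable key order and rounded floats."""
    with open(path, "w") as fh:
        json.dump(_round_floats(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


_LASER_KEYS = {
    "gamma_G", "gamma_Q", "mu2", "s", "beta", "eta", "emission_exponent",
}
_TOP_KEYS = {
    "preset", "scheme", "outdir", "seed",
    "mu0", "c", "tau_b", "tau_p", "tau_d", "t_pad",
} | _LASER_KEYS


@dataclass
class RunConfig:
    """Typed configuration for CLI runs."""

    preset: str = "paper2023"
    scheme: str = "event"
    outdir: str = "."
    seed: int = 0
    mu0: float | None = None
    c: float | None = None
    tau_b: float = 50.0
    tau_p: float = 30.0
    tau_d: float = 0.0
    t_pad: float = 3000.0
    laser_overrides: dict = field(default_factory=dict)

    def laser_params(self) -> LaserParams:
        base = LaserParams.preset(self.preset)
        return base.replace(**self.laser_overrides) if self.laser_overrides else base

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        text = json.dumps(_round_floats(self.to_dict()), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Parse a flat YAML config file; unknown keys raise ValueError."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a flat key-value mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if raw.get("preset", "paper2023") not in PRESETS:
        raise ValueError(f"unknown preset {raw.get('preset')!r}")
    overrides = {k: raw.pop(k) for k in list(raw) if k in _LASER_KEYS}
    cfg = RunConfig(**raw)
    cfg.laser_overrides = overrides
    cfg.laser_params()  # validates overrides
    return cfg


def package_version() -> str:
    try:
        return _pkg_version("microspike")
    except PackageNotFoundError:  # pragma: no cover - dev tree
        return "unknown"


def write_provenance(outdir, config: RunConfig | dict, seed: int | None = None) -> Path:
    """Write a provenance JSON (config hash, version, seed) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(config, RunConfig):
        cfg_dict = config.to_dict()
        cfg_hash = config.config_hash()
        seed = config.seed if seed is None else seed
    else:
        cfg_dict = dict(config)
        cfg_hash = hashlib.sha256(
            json.dumps(_round_floats(cfg_dict), sort_keys=True).encode()
        ).hexdigest()[:16]
    payload = {
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "microspike_version": package_version(),
        "seed": seed,
    }
    path = outdir / "provenance.json"
    dump_json(payload, path)
    return path
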