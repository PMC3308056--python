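"""Run configuration: defaults, YAML files, and flag precedence.

Resolution order is CLI flag > YAML file > built-in default, and the
provenance of every resolved value is recorded so a run log can state where
each parameter came from.  Defaults mirror the published tool behaviour:
trim 0, ten-fold tailcurve threshold, +/- 15 bp error-pattern window,
automatic average-quality cutoff, seed 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .cascade import CascadeParams

SUBCOMMANDS = ("call", "simulate", "evaluate")

#: built-in defaults shared by the CLI and YAML path
DEFAULTS: dict[str, Any] = {
    "alleles": 80,
    "trim": 0,
    "tailcurve_max": 10.0,
    "flank": 15,
    "avg_quality_cutoff": None,  # automatic clustering
    "waf_floor": None,  # 0.25 / alleles
    "seed": 1,
    "manifest": None,
    "regions": None,
    "reference": None,
    "out": None,
    "report": None,
    "calls": None,
    "truth": None,
    "preset": "cohort1",
    "read_length": 47,
    "disable_cluster": False,
    "disable_quality": False,
    "disable_tailcurve": False,
    "disable_error_model": False,
}

_REQUIRED = {
    "call": ("manifest", "regions", "reference", "out"),
    "simulate": ("out",),
    "evaluate": ("calls", "truth", "out"),
}

_TYPES: dict[str, type] = {
    "alleles": int, "trim": int, "flank": int, "seed": int, "read_length": int,
    "tailcurve_max": float,
}


@dataclass
class RunConfig:
    """A fully resolved configuration for one subcommand invocation."""

    subcommand: str
    values: dict[str, Any]
    provenance: dict[str, str] = field(default_factory=dict)

    def __getattr__(self, name: str) -> Any:
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name)

    def cascade_params(self) -> CascadeParams:
        v = self.values
        return CascadeParams(
            alleles_per_pool=v["alleles"],
            waf_floor=v["waf_floor"],
            trim=v["trim"],
            tailcurve_max=v["tailcurve_max"],
            flank=v["flank"],
            avg_quality_cutoff=v["avg_quality_cutoff"],
            seed=v["seed"],
            enable_cluster=not v["disable_cluster"],
            enable_quality=not v["disable_quality"],
            enable_tailcurve=not v["disable_tailcurve"],
            enable_error_model=not v["disable_error_model"],
        )

    def to_dict(self) -> dict[str, Any]:
        return {"subcommand": self.subcommand, **self.values}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def parse_and_validate(
    subcommand: str,
    flags: Mapping[str, Any] | None = None,
    yaml_path: str | Path | None = None,
) -> RunConfig:
    """Resolve a configuration from defaults, an optional YAML file, and the
    flags actually provided on the command line (``flags`` holds only those).
    """
    if subcommand not in SUBCOMMANDS:
        raise ValueError(f"unknown subcommand {subcommand!r}")
    values = dict(DEFAULTS)
    provenance = {k: "default" for k in values}

    if yaml_path is not None:
        with open(yaml_path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{yaml_path}: YAML config must be a mapping")
        doc.pop("subcommand", None)
        unknown = set(doc) - set(values)
        if unknown:
            raise ValueError(f"{yaml_path}: unknown keys {sorted(unknown)}")
        for k, v in doc.items():
            values[k] = _coerce(k, v)
            provenance[k] = "file"

    for k, v in (flags or {}).items():
        if k not in values:
            raise ValueError(f"unknown flag {k!r}")
        if v is None:
            continue  # flag not provided
        values[k] = _coerce(k, v)
        provenance[k] = "flag"

    _validate(subcommand, values)
    return RunConfig(subcommand=subcommand, values=values, provenance=provenance)


def _coerce(key: str, value: Any) -> Any:
    if value is None:
        return None
    t = _TYPES.get(key)
    if t is None:
        return value
    try:
        return t(value)
    except (TypeError, ValueError):
        raise ValueError(f"parameter {key!r} expects {t.__name__}, got {value!r}")


def _validate(subcommand: str, values: dict[str, Any]) -> None:
    if values["alleles"] < 2:
        raise ValueError("alleles must be >= 2 (a pool carries many alleles)")
    if values["trim"] < 0 or values["flank"] < 0 or values["seed"] < 0:
        raise ValueError("trim, flank and seed must be >= 0")
    if values["tailcurve_max"] < 1:
        raise ValueError("tailcurve_max must be >= 1 (it is a fold change)")
    for key in _REQUIRED[subcommand]:
        if values[key] is None:
            raise ValueError(f"'{subcommand}' requires --{key.replace('_', '-')}")


def roundtrip(cfg: RunConfig) -> RunConfig:
    """Re-parse an emitted configuration; the result equals the original."""
    d = cfg.to_dict()
    sub = d.pop("subcommand")
    return parse_and_validate(sub, flags=d)


def equal(a: RunConfig, b: RunConfig) -> bool:
    return a.subcommand == b.subcommand and a.values == b.values


__all__ = [
    "RunConfig", "parse_and_validate", "roundtrip", "equal",
    "DEFAULTS", "SUBCOMMANDS",
]
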