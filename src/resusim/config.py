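"""Configuration loading, validation and provenance digests.

The config dialect is TOML (frozen choice). An empty or absent file
yields the documented defaults; unknown keys are rejected by name; every
loaded configuration carries a sha256 digest of its fully resolved
contents so reports can be tied to the exact parameterization.

Sections: [plant] (population-median physiology), [population]
(lognormal dispersions), [target], [clamp_schedule],
[controller.pi|fuzzy|combined|manual_f|manual_fne], [protocol].
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import tomllib
from pathlib import Path

from . import controllers as ctl
from . import plant as pl
from .protocol import ProtocolConfig

__all__ = ["ConfigError", "load_config", "build_config", "config_digest",
           "config_to_dict", "dump_config"]


class ConfigError(ValueError):
    """A config file key is unknown or violates a constraint."""


def _take_section(data: dict, name: str) -> dict:
    sec = data.pop(name, {})
    if not isinstance(sec, dict):
        raise ConfigError(f"section [{name}] must be a table")
    return sec


def _apply(section: dict, cls, section_name: str, **extra):
    """Build dataclass ``cls`` from defaults overridden by ``section``."""
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section_name}]: {sorted(unknown)}; "
            f"valid keys: {sorted(valid)}"
        )
    try:
        return cls(**{**section, **extra})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in [{section_name}]: {exc}") from exc


def _parse_error_sets(raw) -> tuple[ctl.FuzzySet, ...]:
    sets = []
    for row in raw:
        label, a, b, c = row
        sets.append(ctl.FuzzySet(str(label), float(a), float(b), float(c)))
    return tuple(sets)


def build_config(data: dict) -> ProtocolConfig:
    """Resolve a parsed TOML mapping into a full ProtocolConfig."""
    data = dict(data)

    plant_sec = _take_section(data, "plant")
    medians = _apply(plant_sec, pl.PlantParams, "plant")

    pop_sec = _take_section(data, "population")
    dispersions = dict(pl.DEFAULT_DISPERSIONS)
    for key, val in pop_sec.items():
        dispersions[key] = float(val)
    try:
        population = pl.PopulationSpec(medians=medians, dispersions=dispersions)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    target = _apply(_take_section(data, "target"), ctl.TargetSpec, "target")
    clamp = _apply(
        _take_section(data, "clamp_schedule"), ctl.ClampSchedule, "clamp_schedule"
    )

    controller = _take_section(data, "controller")
    pi_sec = _take_section(controller, "pi")
    pi_sec.pop("target", None), pi_sec.pop("clamp", None)
    pi = _apply(pi_sec, ctl.PIConfig, "controller.pi", target=target, clamp=clamp)

    fuzzy_sec = _take_section(controller, "fuzzy")
    if "error_sets" in fuzzy_sec:
        fuzzy_sec["error_sets"] = _parse_error_sets(fuzzy_sec["error_sets"])
    fuzzy_sec.pop("target", None), fuzzy_sec.pop("clamp", None)
    fuzzy = _apply(
        fuzzy_sec, ctl.FuzzyConfig, "controller.fuzzy", target=target, clamp=clamp
    )

    comb_sec = _take_section(controller, "combined")
    ne_singletons = comb_sec.pop("ne_singletons", dict(ctl.DEFAULT_NE_SETS))
    ne_error_sets = comb_sec.pop("ne_error_sets", None)
    ne_fuzzy = ctl.FuzzyConfig(
        target=target,
        error_sets=(
            _parse_error_sets(ne_error_sets)
            if ne_error_sets is not None
            else ctl.DEFAULT_ERROR_SETS
        ),
        output_singletons={k: float(v) for k, v in ne_singletons.items()},
        clamp=None,
    )
    comb_sec.pop("pi", None), comb_sec.pop("fuzzy", None)
    combined = _apply(
        comb_sec, ctl.CombinedConfig, "controller.combined", pi=pi, fuzzy=ne_fuzzy
    )

    manual_f = _apply(
        _take_section(controller, "manual_f"), ctl.ManualFConfig,
        "controller.manual_f",
    )
    mfne_sec = _take_section(controller, "manual_fne")
    if "escalation_steps" in mfne_sec:
        mfne_sec["escalation_steps"] = tuple(
            float(x) for x in mfne_sec["escalation_steps"]
        )
    manual_fne = _apply(mfne_sec, ctl.ManualFNEConfig, "controller.manual_fne")
    if controller:
        raise ConfigError(f"unknown [controller.*] section(s): {sorted(controller)}")

    proto_sec = _take_section(data, "protocol")
    if data:
        raise ConfigError(f"unknown top-level section(s)/key(s): {sorted(data)}")
    return _apply(
        proto_sec, ProtocolConfig, "protocol",
        target=target, clamp_schedule=clamp, pi=pi, fuzzy=fuzzy,
        combined=combined, manual_f=manual_f, manual_fne=manual_fne,
        population=population,
    )


def load_config(path: str | Path | None = None) -> ProtocolConfig:
    """Load a TOML config file; None or an empty file gives all defaults."""
    if path is None:
        return build_config({})
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return build_config(data)


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return repr(obj)  # 'inf' / '-inf' markers for shoulder sets
    return obj


def config_to_dict(config: ProtocolConfig) -> dict:
    return dataclasses.asdict(config)


def config_digest(config: ProtocolConfig) -> str:
    """sha256 over the canonical JSON of the resolved configuration."""
    payload = json.dumps(_sanitize(config_to_dict(config)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        return repr(v)
    if isinstance(v, int):
        return str(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise TypeError(f"cannot render {type(v)} as TOML")


def _emit_section(name: str, mapping: dict, lines: list[str]) -> None:
    lines.append(f"[{name}]")
    for key, val in mapping.items():
        lines.append(f"{key} = {_toml_scalar(val)}")
    lines.append("")


def dump_config(config: ProtocolConfig | None = None) -> str:
    """Render the fully resolved configuration as TOML (round-trippable
    through load_config)."""
    cfg = config or ProtocolConfig()

    def fields_of(obj, skip=()):
        return {
            f.name: getattr(obj, f.name)
            for f in dataclasses.fields(obj)
            if f.name not in skip
        }

    lines: list[str] = []
    _emit_section("plant", fields_of(cfg.population.medians), lines)
    _emit_section("population", dict(sorted(cfg.population.dispersions.items())), lines)
    _emit_section("target", fields_of(cfg.target), lines)
    _emit_section("clamp_schedule", fields_of(cfg.clamp_schedule), lines)
    _emit_section("controller.pi", fields_of(cfg.pi, skip=("target", "clamp")), lines)

    fz = fields_of(cfg.fuzzy, skip=("target", "clamp", "error_sets", "output_singletons"))
    lines.append("[controller.fuzzy]")
    for key, val in fz.items():
        lines.append(f"{key} = {_toml_scalar(val)}")
    lines.append(
        "error_sets = ["
        + ", ".join(
            _toml_scalar([s.label, s.a, s.b, s.c]) for s in cfg.fuzzy.error_sets
        )
        + "]"
    )
    lines.append("")
    _emit_section(
        "controller.fuzzy.output_singletons", cfg.fuzzy.output_singletons, lines
    )

    comb = fields_of(cfg.combined, skip=("pi", "fuzzy"))
    _emit_section("controller.combined", comb, lines)
    _emit_section(
        "controller.combined.ne_singletons",
        cfg.combined.fuzzy.output_singletons, lines,
    )
    _emit_section("controller.manual_f", fields_of(cfg.manual_f), lines)
    _emit_section("controller.manual_fne", fields_of(cfg.manual_fne), lines)
    proto = fields_of(
        cfg,
        skip=("target", "clamp_schedule", "pi", "fuzzy", "combined",
              "manual_f", "manual_fne", "population"),
    )
    _emit_section("protocol", proto, lines)
    return "\n".join(lines)
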