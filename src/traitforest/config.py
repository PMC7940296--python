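"""TOML run-configuration loading and validation.

A run configuration describes sites, the climate baseline, trait bounds,
trade-off curve sets, herbivory settings, gap-model parameters, scenario
deltas and the experiment design. See ``examples/experiment.toml`` in the
repository for an annotated example. Only keys matching the dataclass
fields are accepted — typos fail loudly.
"""
from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Any

from .dynamics import GapModelParams
from .experiments import ExperimentConfig
from .forcing import ClimateParams, SitePlan
from .herbivory import HerbivorySettings
from .traits import ConfigurationError, TradeoffCurve, TraitBounds

__all__ = ["load_config", "load_experiment_config", "validate_config"]


def _build(cls, section: dict[str, Any], where: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in [{where}]")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid [{where}] section: {exc}") from exc


def _curves_from_section(section: dict[str, Any]) -> dict[str, TradeoffCurve]:
    curves = {}
    for name, spec in section.items():
        curves[name] = _build(
            TradeoffCurve, {"dependent_name": name, **spec}, f"tradeoffs.{name}"
        )
    return curves


def load_config(path) -> dict[str, Any]:
    """Parse a TOML file into validated component objects.

    Returns a dict with whichever of ``sites``, ``climate``, ``bounds``,
    ``gap_params``, ``herbivory``, ``tradeoffs_local``, ``tradeoffs_global``,
    ``experiment`` the file defines.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    out: dict[str, Any] = {}
    if "sites" in raw:
        out["sites"] = tuple(
            _build(SitePlan, s, "sites") for s in raw["sites"]
        )
    if "climate" in raw:
        out["climate"] = _build(ClimateParams, raw["climate"], "climate")
    if "bounds" in raw:
        out["bounds"] = _build(TraitBounds, raw["bounds"], "bounds")
    if "gap_model" in raw:
        out["gap_params"] = _build(GapModelParams, raw["gap_model"], "gap_model")
    if "herbivory" in raw:
        out["herbivory"] = _build(HerbivorySettings, raw["herbivory"], "herbivory")
    if "tradeoffs" in raw:
        for provenance in ("local", "global"):
            if provenance in raw["tradeoffs"]:
                out[f"tradeoffs_{provenance}"] = _curves_from_section(
                    raw["tradeoffs"][provenance]
                )
    if "experiment" in raw:
        out["experiment"] = dict(raw["experiment"])
    if "scenario" in raw:
        sc = raw["scenario"]
        out["scenario"] = (float(sc.get("delta_t_c", 0.0)), float(sc.get("delta_p_frac", 0.0)))
    if "reference_npp" in raw:
        out["reference_npp"] = {float(k): float(v) for k, v in raw["reference_npp"].items()}
    return out


def load_experiment_config(path, seed: int | None = None, outdir=None) -> ExperimentConfig:
    """Assemble an :class:`ExperimentConfig` from a TOML file plus overrides."""
    parts = load_config(path)
    exp = parts.get("experiment", {})
    kwargs: dict[str, Any] = {}
    for key in ("sites", "climate", "bounds", "gap_params", "herbivory", "scenario", "reference_npp"):
        if key in parts:
            kwargs[key] = parts[key]
    if "tradeoffs_local" in parts:
        kwargs["curves_local"] = parts["tradeoffs_local"]
    if "tradeoffs_global" in parts:
        kwargs["curves_global"] = parts["tradeoffs_global"]
    for key in ("years", "average_window", "seed"):
        if key in exp:
            kwargs[key] = int(exp[key])
    if "modes" in exp:
        kwargs["modes"] = tuple(exp["modes"])
    if seed is not None:
        kwargs["seed"] = seed
    if outdir is not None:
        kwargs["outdir"] = Path(outdir)
    return ExperimentConfig(**kwargs)


def validate_config(path) -> list[str]:
    """Validate a TOML configuration; returns human-readable findings."""
    findings = []
    parts = load_config(path)
    findings.append(f"parsed sections: {sorted(parts)}")
    try:
        load_experiment_config(path)
        findings.append("experiment configuration: OK")
    except ConfigurationError as exc:
        findings.append(f"experiment configuration: INVALID ({exc})")
        raise
    return findings
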