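"""Default configuration: every calibrated constant in one record.

The configuration is a plain nested dict (round-trippable through YAML or
JSON without loss) holding the involution estimates, the homeostasis
baseline, all three bounds columns, the physiological ranges, the fixed
infant calibration capacities, the scenario constants and the numerical
settings.  ``config_to_objects`` turns it back into the typed parameter
objects used by the library.
"""

from __future__ import annotations

import json
from dataclasses import asdict, fields
from pathlib import Path
from typing import Any, NamedTuple

import yaml

from .homeostasis import (CALIBRATION_INFANT_CAPACITIES, PARAM_NAMES,
                          HomeostasisParams, SimulationSettings)
from .involution import CarryingCapacities, InvolutionParams, MorphometryParams
from .screening import (EXPERIMENTAL_BOUNDS, GENERALIZED_BOUNDS,
                        MODEL_BASED_BOUNDS, ParameterBounds,
                        PhysiologicalRanges)
from .scenarios import BLOCKED_EGRESS, EARLY_INVOLUTION_EC50, HEALTHY_EGRESS

__all__ = ["make_default_config", "save_config", "load_config",
           "config_to_objects", "ConfigObjects"]


class ConfigObjects(NamedTuple):
    involution: InvolutionParams
    morphometry: MorphometryParams
    homeostasis: HomeostasisParams
    bounds: ParameterBounds
    ranges: PhysiologicalRanges
    infant_capacities: CarryingCapacities
    settings: SimulationSettings


def _bounds_dict(b: ParameterBounds) -> dict[str, list[float]]:
    return {nm: [float(b[nm][0]), float(b[nm][1])] for nm in PARAM_NAMES}


def make_default_config() -> dict[str, Any]:
    """Full default configuration with every shipped constant."""
    settings = SimulationSettings()
    return {
        "involution": asdict(InvolutionParams()),
        "morphometry": asdict(MorphometryParams()),
        "homeostasis": asdict(HomeostasisParams()),
        "bounds": {
            "experimental": _bounds_dict(EXPERIMENTAL_BOUNDS),
            "model_based": _bounds_dict(MODEL_BASED_BOUNDS),
            "generalized": _bounds_dict(GENERALIZED_BOUNDS),
        },
        "physiological_ranges": {
            nm: [float(v) for v in getattr(PhysiologicalRanges(), nm)]
            for nm in ("dn", "dp", "sp4", "sp8")
        },
        "infant_capacities": {
            "t_cort_max": CALIBRATION_INFANT_CAPACITIES.t_cort_max,
            "t_med_max": CALIBRATION_INFANT_CAPACITIES.t_med_max,
        },
        "scenarios": {
            "healthy_egress": list(HEALTHY_EGRESS),
            "blocked_egress": list(BLOCKED_EGRESS),
            "early_involution_ec50": EARLY_INVOLUTION_EC50,
        },
        "settings": {f.name: getattr(settings, f.name)
                     for f in fields(SimulationSettings)
                     if f.name != "output_grid"},
    }


def save_config(cfg: dict[str, Any], path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        raise ValueError(f"unsupported config format {path.suffix!r} (use .yaml/.json)")


def load_config(path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    raise ValueError(f"unsupported config format {path.suffix!r} (use .yaml/.json)")


def config_to_objects(cfg: dict[str, Any], bounds_column: str = "generalized") -> ConfigObjects:
    """Validate a configuration dict into typed parameter objects."""
    ranges = PhysiologicalRanges(**{k: tuple(v) for k, v in
                                    cfg["physiological_ranges"].items()})
    bounds = ParameterBounds({k: tuple(v) for k, v in
                              cfg["bounds"][bounds_column].items()})
    return ConfigObjects(
        involution=InvolutionParams(**cfg["involution"]),
        morphometry=MorphometryParams(**cfg["morphometry"]),
        homeostasis=HomeostasisParams(**cfg["homeostasis"]),
        bounds=bounds,
        ranges=ranges,
        infant_capacities=CarryingCapacities(**cfg["infant_capacities"]),
        settings=SimulationSettings(**cfg["settings"]),
    )
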