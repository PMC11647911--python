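"""Serialization of scenario, method, and study configuration (YAML/JSON).

A configuration document has up to three sections::

    scenario:             # ScenarioParams fields, or preset: calibrated|as_printed
      preset: calibrated
      n_subjects: 1000
    methods:              # list of method specs
      - scheme: sr
      - scheme: upfront
        estimator: wipw
        c_t: 1.0
      - scheme: sequential
        c_t: 0.5
    study:
      reps: 500
      seed: 1
      alpha: 0.05
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .engine import MethodConfig
from .harness import StudyConfig
from .scenario import ScenarioParams, as_printed, calibrated

_PRESETS = {"calibrated": calibrated, "as_printed": as_printed}


def scenario_from_dict(spec: dict) -> ScenarioParams:
    spec = dict(spec or {})
    preset = spec.pop("preset", "calibrated")
    if preset not in _PRESETS:
        raise ValueError(f"unknown scenario preset {preset!r}")
    for key in ("gamma1", "gamma2"):
        if key in spec:
            spec[key] = tuple(spec[key])
    return _PRESETS[preset](**spec)


def method_from_dict(spec: dict) -> MethodConfig:
    return MethodConfig(**spec)


def load_config(path) -> StudyConfig:
    """Read a YAML or JSON study configuration."""
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    params = scenario_from_dict(doc.get("scenario", {}))
    methods = [method_from_dict(m) for m in doc.get("methods", [{"scheme": "sr"}])]
    study = doc.get("study", {})
    return StudyConfig(params=params, methods=methods, **study)


def dump_scenario(params: ScenarioParams, path) -> None:
    doc = dataclasses.asdict(params)
    doc["gamma1"] = list(doc["gamma1"])
    doc["gamma2"] = list(doc["gamma2"])
    Path(path).write_text(yaml.safe_dump({"scenario": doc}, sort_keys=False))
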