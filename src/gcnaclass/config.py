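"""Single-document configuration: thresholds, rule tables, generator
parameters.  YAML or JSON; anything omitted falls back to defaults."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .cna import Thresholds
from .simulate import GeneratorConfig


def default_config() -> dict:
    return {
        "thresholds": asdict(Thresholds()),
        "generator": _generator_to_dict(GeneratorConfig()),
        "mds": {"k": 2, "metric": "euclidean"},
        "survival": {"ties": "efron", "age_cutoff": 45.0},
        "validation": {"baseline": ["W1"], "merge_candidate": ["W1", "W2"], "alpha": 0.05},
    }


def _generator_to_dict(g: GeneratorConfig) -> dict:
    d = asdict(g)
    d["age_params"] = {cl: [list(c) for c in comps] for cl, comps in g.age_params.items()}
    return d


def load_config(path: str | Path | None) -> dict:
    """Load a config file and deep-merge it over the defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return _deep_merge(cfg, doc or {})


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def thresholds_from_config(cfg: dict) -> Thresholds:
    return Thresholds(**cfg.get("thresholds", {}))


def generator_from_config(cfg: dict) -> GeneratorConfig:
    return GeneratorConfig.from_dict(cfg.get("generator", {}))
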