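"""YAML configuration loading.

A config file holds up to four blocks — ``pipeline:``, ``net:``, ``pemea:``
and ``ga:`` — each a mapping of the corresponding dataclass's fields; every
default is overridable and unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml

from .bp_network import NetworkConfig
from .hybrid_pipeline import PipelineConfig
from .pemea import GAConfig, PEMEAConfig

__all__ = ["load_config", "config_from_dict"]

_BLOCKS = {"net": NetworkConfig, "pemea": PEMEAConfig, "ga": GAConfig}


def _build(cls, mapping: dict):
    fields = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(mapping) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def config_from_dict(obj: dict) -> PipelineConfig:
    obj = dict(obj or {})
    sub = {}
    for name, cls in _BLOCKS.items():
        if name in obj:
            sub[name] = _build(cls, obj.pop(name) or {})
    pipeline = dict(obj.pop("pipeline", {}) or {})
    if obj:
        raise ValueError(f"unknown top-level config blocks: {sorted(obj)}")
    if "norm_range" in pipeline:
        pipeline["norm_range"] = tuple(pipeline["norm_range"])
    return _build(PipelineConfig, {**pipeline, **sub})


def load_config(path: Optional[str]) -> PipelineConfig:
    """Load a pipeline config from YAML; None gives all defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    return config_from_dict(yaml.safe_load(text) or {})
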