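"""YAML/JSON run configuration mirroring every tunable threshold."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import yaml

from .blink import BlinkConfig
from .boundaries import BoundaryState
from .pipeline import PipelineConfig

__all__ = ["load_pipeline_config"]


def load_pipeline_config(
    path: Union[str, Path, None] = None,
    model_path: Union[str, Path, None] = None,
) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from an optional YAML/JSON file.

    Recognized top-level keys: ``blink`` (mapping onto :class:`BlinkConfig`
    fields), ``poor_signal_max``, ``smoothing``, ``ewma_alpha``,
    ``blink_enabled``, ``clamp_max`` and ``model`` (path to a fitted boundary
    JSON, overridden by ``model_path``).  Missing keys keep their defaults.
    """
    doc = {}
    if path is not None:
        text = Path(path).read_text()
        doc = (json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)) or {}
    blink_doc = doc.get("blink", {})
    if "dip_band" in blink_doc:
        blink_doc["dip_band"] = tuple(blink_doc["dip_band"])
    model = model_path or doc.get("model")
    boundary = BoundaryState.from_json(model) if model else BoundaryState()
    kwargs = {
        k: doc[k]
        for k in ("poor_signal_max", "smoothing", "ewma_alpha", "blink_enabled", "clamp_max")
        if k in doc
    }
    return PipelineConfig(boundary=boundary, blink=BlinkConfig(**blink_doc), **kwargs)
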