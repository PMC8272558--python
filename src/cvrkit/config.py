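"""Run configuration: protocol cards, phantom conditions, experiment switches.

A single YAML file mirrors the acquisition protocol blocks (one block per
technique, keys named after the protocol-card rows), the cohort physiology
distributions, and the experiment-mode switches.  ``load_config`` starts
from the packaged defaults and deep-merges an optional user file plus
keyword overrides on top.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .asl import AslProtocol
from .core import ValidationError
from .phantom import PhantomSpec, TissueClassParams


def _default_text() -> str:
    return (importlib.resources.files("cvrkit") / "data" /
            "default_config.yaml").read_text()


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None, **overrides) -> dict:
    config = yaml.safe_load(_default_text())
    if path is not None:
        user = yaml.safe_load(Path(path).read_text())
        if user:
            config = _deep_merge(config, user)
    if overrides:
        config = _deep_merge(config, overrides)
    return config


def protocols_from_config(config: dict) -> dict[str, AslProtocol]:
    out: dict[str, AslProtocol] = {}
    blocks = config.get("protocols", {})
    if not blocks:
        raise ValidationError("config has no protocol blocks")
    common = config.get("quantification", {})
    for name, block in blocks.items():
        kwargs = dict(
            technique=block.get("technique", name),
            bolus_duration=float(block["bolus_duration_ms"]),
            plds=tuple(float(p) for p in block.get("pld_ms", [])),
            ti=block.get("inversion_time_ms"),
            vc=block.get("vc_cm_s"),
            tr=block.get("tr_ms"),
            t1_tissue=float(common.get("t1_tissue_s", 1.3)),
            partition_coefficient=float(common.get("partition_coefficient", 0.9)),
        )
        if "labeling_efficiency" in block:
            kwargs["labeling_efficiency"] = float(block["labeling_efficiency"])
        out[name] = AslProtocol(**kwargs)
    return out


def phantom_spec_from_config(config: dict, seed: int | None = None) -> PhantomSpec:
    block = dict(config.get("phantom", {}))
    for cls in ("gm", "wm", "csf"):
        if cls in block and isinstance(block[cls], dict):
            block[cls] = TissueClassParams(**block[cls])
    if "grid_shape" in block:
        block["grid_shape"] = tuple(block["grid_shape"])
    if "voxel_size" in block:
        block["voxel_size"] = tuple(block["voxel_size"])
    if seed is not None:
        block["seed"] = seed
    return PhantomSpec(**block)
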