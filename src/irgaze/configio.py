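"""YAML round-trip for device geometry, render, network and cascade configs.

One top-level file can bundle everything the pipeline needs under the keys
``device``, ``render``, ``cascade`` and ``train``; each section can also
live in its own file.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .geometry import DeviceGeometry
from .nn.cascade import CascadeConfig
from .nn.config import ConvSpec, NetConfig
from .nn.train import TrainProtocol
from .synth import RenderConfig

__all__ = [
    "device_to_dict", "device_from_dict", "load_device", "save_device",
    "net_to_dict", "net_from_dict", "cascade_to_dict", "cascade_from_dict",
    "load_config", "save_config",
]


def _tupleize(obj):
    if isinstance(obj, (list, tuple)):
        return tuple(_tupleize(v) for v in obj)
    return obj


def device_to_dict(dev: DeviceGeometry) -> Dict[str, Any]:
    d = asdict(dev)
    return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def device_from_dict(d: Dict[str, Any]) -> DeviceGeometry:
    kwargs = {k: _tupleize(v) for k, v in d.items()}
    return DeviceGeometry(**kwargs)


def save_device(dev: DeviceGeometry, path) -> None:
    Path(path).write_text(yaml.safe_dump(device_to_dict(dev), sort_keys=False))


def load_device(path) -> DeviceGeometry:
    return device_from_dict(yaml.safe_load(Path(path).read_text()))


def render_to_dict(cfg: RenderConfig) -> Dict[str, Any]:
    d = asdict(cfg)
    return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def render_from_dict(d: Dict[str, Any]) -> RenderConfig:
    return RenderConfig(**{k: _tupleize(v) for k, v in d.items()})


def net_to_dict(cfg: NetConfig) -> Dict[str, Any]:
    return {
        "input_size": cfg.input_size,
        "downscale": cfg.downscale,
        "conv_layers": [asdict(c) for c in cfg.conv_layers],
        "dense_layers": list(cfg.dense_layers),
        "dropout": cfg.dropout,
        "head": cfg.head,
    }


def net_from_dict(d: Dict[str, Any]) -> NetConfig:
    return NetConfig(
        input_size=d["input_size"], downscale=d.get("downscale", 1),
        conv_layers=[ConvSpec(**c) for c in d["conv_layers"]],
        dense_layers=list(d.get("dense_layers", [])),
        dropout=d.get("dropout", 0.5), head=d.get("head", "center_of_mass"))


def cascade_to_dict(cc: CascadeConfig) -> Dict[str, Any]:
    return {"validity_threshold": cc.validity_threshold,
            "nets": {role: net_to_dict(c) for role, c in cc.nets.items()}}


def cascade_from_dict(d: Dict[str, Any]) -> CascadeConfig:
    return CascadeConfig(
        nets={role: net_from_dict(c) for role, c in d["nets"].items()},
        validity_threshold=d.get("validity_threshold", 0.5))


def load_config(path) -> Dict[str, Any]:
    """Load a bundled config file into instantiated sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: Dict[str, Any] = {}
    if "device" in raw:
        out["device"] = device_from_dict(raw["device"])
    if "render" in raw:
        out["render"] = render_from_dict(raw["render"])
    if "cascade" in raw:
        out["cascade"] = cascade_from_dict(raw["cascade"])
    if "train" in raw:
        out["train"] = TrainProtocol(**raw["train"])
    return out


def save_config(path, device: Optional[DeviceGeometry] = None,
                render: Optional[RenderConfig] = None,
                cascade: Optional[CascadeConfig] = None,
                train: Optional[TrainProtocol] = None) -> None:
    raw: Dict[str, Any] = {}
    if device is not None:
        raw["device"] = device_to_dict(device)
    if render is not None:
        raw["render"] = render_to_dict(render)
    if cascade is not None:
        raw["cascade"] = cascade_to_dict(cascade)
    if train is not None:
        raw["train"] = asdict(train)
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
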