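"""Serialization of trained networks (topology embedded with the weights)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .network import Network, _BatchNormLayer
from .topology import TopologySpec
from .trainer import TrainConfig, TrainedModel

_FORMAT_VERSION = 1


def _state_arrays(net: Network) -> list[np.ndarray]:
    arrays: list[np.ndarray] = []
    for layer in net.layers:
        for p in layer.params():
            arrays.append(p.value)
        if isinstance(layer, _BatchNormLayer):
            arrays.append(layer.running_mean)
            arrays.append(layer.running_var)
    return arrays


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write weights, topology, config, classes and log to one .npz file."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "topology": model.topology.to_dict(),
        "config": model.config.to_dict(),
        "classes": [str(c) for c in model.classes],
        "training_log": model.training_log,
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(_state_arrays(model.network))}
    np.savez(Path(path), meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format {meta.get('format_version')}")
        spec = TopologySpec.from_dict(meta["topology"])
        net = Network(spec, np.random.default_rng(0))
        targets = _state_arrays(net)
        for i, target in enumerate(targets):
            stored = data[f"arr_{i}"]
            if stored.shape != target.shape:
                raise ValueError("stored weights inconsistent with topology")
            target[...] = stored
    return TrainedModel(
        topology=spec,
        network=net,
        training_log=meta["training_log"],
        config=TrainConfig.from_dict(meta["config"]),
        classes=np.asarray(meta["classes"]),
    )
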