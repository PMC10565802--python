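"""Network configs as YAML, weights as named-array archives."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .network import (
    ConfigurationError,
    ConvSpec,
    DenseSpec,
    Network,
    NetworkSpec,
    NeuronParams,
    PoolSpec,
    build_network,
)

__all__ = [
    "spec_to_dict",
    "spec_from_dict",
    "save_spec",
    "load_spec",
    "save_weights",
    "load_weights",
    "save_network",
    "load_network",
]

_LAYER_KINDS = {"conv": ConvSpec, "pool": PoolSpec, "dense": DenseSpec}
_KIND_NAMES = {ConvSpec: "conv", PoolSpec: "pool", DenseSpec: "dense"}


def spec_to_dict(spec: NetworkSpec) -> dict:
    layers = []
    for ls in spec.layers:
        d = asdict(ls)
        d["kind"] = _KIND_NAMES[type(ls)]
        layers.append(d)
    return {
        "layers": layers,
        "input_shape": list(spec.input_shape),
        "n_classes": spec.n_classes,
        "seed": spec.seed,
    }


def spec_from_dict(data: dict) -> NetworkSpec:
    layers = []
    for d in data["layers"]:
        d = dict(d)
        kind = d.pop("kind")
        if kind not in _LAYER_KINDS:
            raise ConfigurationError(f"unknown layer kind {kind!r}")
        neuron = d.pop("neuron", None)
        if neuron is not None:
            d["neuron"] = NeuronParams(**neuron)
        layers.append(_LAYER_KINDS[kind](**d))
    return NetworkSpec(
        layers=tuple(layers),
        input_shape=tuple(data["input_shape"]),
        n_classes=int(data["n_classes"]),
        seed=int(data.get("seed", 0)),
    )


def save_spec(spec: NetworkSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def load_spec(path) -> NetworkSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


def save_weights(net: Network, path) -> None:
    np.savez(path, **net.get_weights())


def load_weights(net: Network, path) -> Network:
    with np.load(path) as archive:
        net.set_weights(dict(archive))
    return net


def save_network(net: Network, spec_path, weights_path) -> None:
    save_spec(net.spec, spec_path)
    save_weights(net, weights_path)


def load_network(spec_path, weights_path=None) -> Network:
    net = build_network(load_spec(spec_path))
    if weights_path is not None:
        load_weights(net, weights_path)
    return net
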