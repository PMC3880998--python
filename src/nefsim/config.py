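"""JSON model configuration: serialize and reload symbolic models.

Matrices are stored as nested arrays and object references by name (with a
``"<ensemble>.neurons"`` suffix for neuron-level endpoints).  Callable node
outputs and decoded functions are referenced through a name registry —
register custom functions with :func:`register_function` before saving or
loading models that use them.
"""

from __future__ import annotations

import json

import numpy as np

from .model import (
    ConnectionSpec,
    EnsembleSpec,
    ModelSpec,
    NetworkSpec,
    NeuronView,
    NodeSpec,
    ProbeSpec,
)
from .neurons import LIFParams

__all__ = [
    "register_function",
    "to_config",
    "from_config",
    "save_model",
    "load_model",
]

FUNCTIONS: dict = {}


def register_function(name: str, fn) -> None:
    """Make ``fn`` serializable under ``name`` in model configs."""
    FUNCTIONS[name] = fn


def _fn_name(fn) -> str:
    for name, registered in FUNCTIONS.items():
        if registered is fn:
            return name
    raise ValueError(
        f"function {fn!r} is not registered; call register_function() first"
    )


register_function("square", lambda x: np.asarray(x) ** 2)
register_function("negate", lambda x: -np.asarray(x))
register_function("product_of_dims", lambda x: np.array([x[0] * x[1]]))


def _matrix(value):
    return None if value is None else np.asarray(value).tolist()


def _interval_or_values(value):
    if value is None:
        return None
    if isinstance(value, tuple):
        return {"interval": [float(value[0]), float(value[1])]}
    return {"values": np.asarray(value, dtype=float).tolist()}


def _load_interval(cfg):
    if cfg is None:
        return None
    if "interval" in cfg:
        return tuple(cfg["interval"])
    return np.asarray(cfg["values"], dtype=float)


def _ref(obj) -> str:
    if isinstance(obj, NeuronView):
        return f"{obj.ensemble.name}.neurons"
    return obj.name


def _obj_config(obj) -> dict:
    if isinstance(obj, EnsembleSpec):
        return {
            "kind": "ensemble",
            "name": obj.name,
            "neurons": {"n_neurons": obj.neurons.n_neurons,
                        "tau_rc": obj.neurons.tau_rc,
                        "tau_ref": obj.neurons.tau_ref},
            "dimensions": obj.dimensions,
            "radius": obj.radius,
            "encoders": _matrix(obj.encoders),
            "max_rates": _interval_or_values(obj.max_rates),
            "intercepts": _interval_or_values(obj.intercepts),
            "seed": obj.seed,
        }
    if isinstance(obj, NodeSpec):
        if callable(obj.output):
            output = {"function": _fn_name(obj.output)}
        elif obj.output is None:
            output = None
        else:
            output = {"constant": np.asarray(obj.output).tolist()}
        return {"kind": "node", "name": obj.name, "output": output,
                "size_in": obj.size_in, "size_out": obj.size_out}
    if isinstance(obj, ConnectionSpec):
        return {
            "kind": "connection",
            "name": obj.name,
            "pre": _ref(obj.pre),
            "post": _ref(obj.post),
            "function": None if obj.function is None else _fn_name(obj.function),
            "transform": _matrix(obj.transform),
            "filter_tau": obj.filter_tau,
            "weights": _matrix(obj.weights),
        }
    if isinstance(obj, ProbeSpec):
        return {"kind": "probe", "name": obj.name, "target": obj.target.name,
                "attribute": obj.attribute, "filter_tau": obj.filter_tau,
                "sample_every": obj.sample_every}
    if isinstance(obj, NetworkSpec):
        return {
            "kind": "network",
            "name": obj.name,
            "members": [_obj_config(member) for member in obj.members],
            "inputs": {k: _ref(v) for k, v in obj.inputs.items()},
            "outputs": {k: _ref(v) for k, v in obj.outputs.items()},
        }
    raise TypeError(f"cannot serialize {obj!r}")


def to_config(model: ModelSpec) -> dict:
    """Serialize a model to a JSON-compatible dict."""
    return {
        "name": model.name,
        "seed": model.seed,
        "objects": [_obj_config(obj) for obj in model.objects],
    }


def _resolve_ref(ref: str, registry: dict):
    if ref.endswith(".neurons") and ref[: -len(".neurons")] in registry:
        return registry[ref[: -len(".neurons")]].neuron_view
    if ref not in registry:
        raise ValueError(f"config references unknown object {ref!r}")
    return registry[ref]


def _build_objects(configs, registry, deferred):
    """First pass: construct non-reference objects, defer connections/probes."""
    out = []
    for cfg in configs:
        kind = cfg["kind"]
        if kind == "ensemble":
            enc = cfg.get("encoders")
            obj = EnsembleSpec(
                name=cfg["name"],
                neurons=LIFParams(**cfg["neurons"]),
                dimensions=cfg["dimensions"],
                radius=cfg.get("radius", 1.0),
                encoders=None if enc is None else np.asarray(enc, dtype=float),
                max_rates=_load_interval(cfg.get("max_rates")),
                intercepts=_load_interval(cfg.get("intercepts")),
                seed=cfg.get("seed"),
            )
            registry[obj.name] = obj
        elif kind == "node":
            output = cfg["output"]
            if output is None:
                resolved = None
            elif "function" in output:
                if output["function"] not in FUNCTIONS:
                    raise ValueError(
                        f"node {cfg['name']!r} uses unregistered function "
                        f"{output['function']!r}"
                    )
                resolved = FUNCTIONS[output["function"]]
            else:
                resolved = np.asarray(output["constant"], dtype=float)
            obj = NodeSpec(name=cfg["name"], output=resolved,
                           size_in=cfg.get("size_in", 0),
                           size_out=cfg.get("size_out"))
            registry[obj.name] = obj
        elif kind == "network":
            obj = NetworkSpec(name=cfg["name"])
            obj.members = _build_objects(cfg["members"], registry, deferred)
            deferred.append(("network_io", obj, cfg))
            registry[obj.name] = obj
        elif kind in ("connection", "probe"):
            obj = _Placeholder(cfg)
            deferred.append(("spec", obj, cfg))
        else:
            raise ValueError(f"unknown object kind {kind!r}")
        out.append(obj)
    return out


class _Placeholder:
    def __init__(self, cfg):
        self.cfg = cfg


def _finalize(containers, registry):
    """Second pass: replace placeholders now that every name is known."""
    for container in containers:
        objs = container.objects if isinstance(container, ModelSpec) else container.members
        for i, obj in enumerate(objs):
            if isinstance(obj, _Placeholder):
                cfg = obj.cfg
                if cfg["kind"] == "connection":
                    tf = cfg.get("transform")
                    wt = cfg.get("weights")
                    objs[i] = ConnectionSpec(
                        pre=_resolve_ref(cfg["pre"], registry),
                        post=_resolve_ref(cfg["post"], registry),
                        function=(None if cfg.get("function") is None
                                  else FUNCTIONS[cfg["function"]]),
                        transform=(None if tf is None or wt is not None
                                   else np.asarray(tf, dtype=float)),
                        filter_tau=cfg.get("filter_tau"),
                        weights=None if wt is None else np.asarray(wt, dtype=float),
                        name=cfg["name"],
                    )
                else:
                    objs[i] = ProbeSpec(
                        target=_resolve_ref(cfg["target"], registry),
                        attribute=cfg["attribute"],
                        filter_tau=cfg.get("filter_tau"),
                        sample_every=cfg.get("sample_every"),
                        name=cfg["name"],
                    )
            elif isinstance(obj, NetworkSpec):
                _finalize([obj], registry)


def from_config(config: dict) -> ModelSpec:
    """Reconstruct a model from :func:`to_config` output."""
    registry: dict = {}
    deferred: list = []
    model = ModelSpec(name=config.get("name", "model"), seed=config.get("seed"))
    model.objects = _build_objects(config["objects"], registry, deferred)
    _finalize([model], registry)
    for kind, obj, cfg in deferred:
        if kind == "network_io":
            obj.inputs = {k: _resolve_ref(v, registry)
                          for k, v in cfg.get("inputs", {}).items()}
            obj.outputs = {k: _resolve_ref(v, registry)
                           for k, v in cfg.get("outputs", {}).items()}
    model._counter = len(model.objects)
    return model


def save_model(model: ModelSpec, path) -> None:
    with open(path, "w") as f:
        json.dump(to_config(model), f, indent=1, sort_keys=True)


def load_model(path) -> ModelSpec:
    with open(path) as f:
        return from_config(json.load(f))
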