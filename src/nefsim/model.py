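"""Symbolic model layer: ensembles, nodes, connections, probes, networks.

Objects here are descriptions only — constructing them allocates no
simulation state and runs no neurons.  A :class:`ModelSpec` is handed to
:func:`nefsim.builder.build`, which resolves unspecified attributes
(encoders, gains, decoders) and compiles everything into signals and
operators for the time-stepping engine.  The strict split means one model
can be built repeatedly (different seeds, different dt) without mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .neurons import LIFParams

__all__ = [
    "EnsembleSpec",
    "NeuronView",
    "NodeSpec",
    "ConnectionSpec",
    "ProbeSpec",
    "NetworkSpec",
    "ModelSpec",
    "add_object",
    "connect",
    "probe",
    "validate",
]

#: Valid probe attributes per target kind.
PROBE_ATTRIBUTES = {
    "ensemble": {"decoded_output", "spikes", "voltage", "input_current"},
    "node": {"node_output"},
}

#: Sentinel: use the kind-dependent default synaptic filter (5 ms for
#: ensemble-sourced connections, unfiltered for node-sourced ones).
DEFAULT_FILTER = "default"

#: Default synaptic filter time constant, seconds (fast excitatory synapse).
DEFAULT_SYNAPSE_TAU = 0.005


@dataclass(eq=False)
class EnsembleSpec:
    """A population of neurons representing a d-dimensional real vector.

    ``radius`` scales the represented range: a value ``x`` is encoded as
    ``x / radius``, so the population accurately represents vectors of norm
    up to roughly ``radius``.  Unset attributes (``encoders``, ``max_rates``,
    ``intercepts``) are resolved at build time from seeded defaults
    consistent with cortical pyramidal-cell responses.
    """

    name: Optional[str]
    neurons: LIFParams
    dimensions: int
    radius: float = 1.0
    encoders: Optional[np.ndarray] = None
    max_rates: Optional[Union[tuple, Sequence[float]]] = None
    intercepts: Optional[Union[tuple, Sequence[float]]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.dimensions < 1:
            raise ValueError(f"dimensions must be >= 1, got {self.dimensions}")
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if self.encoders is not None:
            enc = np.atleast_2d(np.asarray(self.encoders, dtype=float))
            if enc.shape != (self.neurons.n_neurons, self.dimensions):
                raise ValueError(
                    f"encoders shape {enc.shape} != "
                    f"({self.neurons.n_neurons}, {self.dimensions})"
                )
            self.encoders = enc

    @property
    def neuron_view(self) -> "NeuronView":
        """Endpoint for direct neuron-level connections (explicit weights)."""
        return NeuronView(self)

    @property
    def size_out(self) -> int:
        return self.dimensions

    @property
    def size_in(self) -> int:
        return self.dimensions


@dataclass(frozen=True)
class NeuronView:
    """Reference to the raw neurons of an ensemble, bypassing decode/encode."""

    ensemble: EnsembleSpec

    @property
    def size_out(self) -> int:
        return self.ensemble.neurons.n_neurons

    size_in = size_out


@dataclass(eq=False)
class NodeSpec:
    """Non-neural computation: a function of (t[, input vector]) -> vector.

    ``output`` may be a callable, a constant vector, or ``None`` for a
    passthrough node that relays its summed input (used by networks to
    expose internal endpoints).
    """

    name: Optional[str]
    output: Union[Callable, Sequence[float], np.ndarray, None]
    size_in: int = 0
    size_out: Optional[int] = None

    def __post_init__(self) -> None:
        if self.size_in < 0:
            raise ValueError("size_in must be >= 0")
        if callable(self.output):
            if self.size_out is None:
                raise ValueError("size_out is required for callable node outputs")
        elif self.output is None:
            if self.size_in < 1:
                raise ValueError("passthrough nodes need size_in >= 1")
            self.size_out = self.size_in
        else:
            self.output = np.atleast_1d(np.asarray(self.output, dtype=float))
            if self.size_out is None:
                self.size_out = self.output.size
            elif self.size_out != self.output.size:
                raise ValueError(
                    f"size_out {self.size_out} != constant output length "
                    f"{self.output.size}"
                )


def _endpoint_size(obj, direction: str) -> int:
    return obj.size_out if direction == "out" else obj.size_in


def _infer_function_size(function: Callable, d: int) -> int:
    """Output dimensionality of a decoded function, probed at the origin."""
    out = np.atleast_1d(np.asarray(function(np.zeros(d)), dtype=float))
    return out.size


@dataclass(eq=False)
class ConnectionSpec:
    """Symbolic edge: how information flows from ``pre`` to ``post``.

    For ensemble sources the decoded value (optionally a ``function`` of it)
    passes through ``transform`` and a first-order synaptic filter with time
    constant ``filter_tau``.  Explicit ``weights`` are only allowed between
    neuron views and replace the decode/transform/encode factorization.
    """

    pre: Union[EnsembleSpec, NodeSpec, NeuronView]
    post: Union[EnsembleSpec, NodeSpec, NeuronView]
    function: Optional[Callable] = None
    transform: Optional[np.ndarray] = None
    filter_tau: Union[float, None, str] = DEFAULT_FILTER
    weights: Optional[np.ndarray] = None
    name: Optional[str] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        pre, post = self.pre, self.post
        if self.weights is not None:
            if not (isinstance(pre, NeuronView) and isinstance(post, NeuronView)):
                raise ValueError(
                    "explicit weights are only permitted between neuron views"
                )
            if self.function is not None or self.transform is not None:
                raise ValueError("weights connections take no function/transform")
            W = np.atleast_2d(np.asarray(self.weights, dtype=float))
            expect = (post.size_in, pre.size_out)
            if W.shape != expect:
                raise ValueError(f"weights shape {W.shape} != expected {expect}")
            self.weights = W
        else:
            if self.function is not None and not isinstance(pre, EnsembleSpec):
                raise ValueError(
                    "a decoded function requires an ensemble source; node and "
                    "neuron outputs pass through the transform only"
                )
            self.transform = self._resolve_transform()
        if self.filter_tau == DEFAULT_FILTER:
            self.filter_tau = (
                DEFAULT_SYNAPSE_TAU
                if isinstance(pre, (EnsembleSpec, NeuronView))
                else None
            )
        if self.filter_tau is not None and self.filter_tau < 0:
            raise ValueError("filter_tau must be non-negative or None")

    @property
    def size_mid(self) -> int:
        """Dimensionality between function output and transform input."""
        if self.function is not None:
            return _infer_function_size(self.function, self.pre.dimensions)
        return _endpoint_size(self.pre, "out")

    def _resolve_transform(self) -> np.ndarray:
        k = self.size_mid
        d_post = _endpoint_size(self.post, "in")
        if self.transform is None:
            if k != d_post:
                raise ValueError(
                    f"cannot use the identity transform: source provides {k} "
                    f"dimensions but target expects {d_post}"
                )
            return np.eye(d_post)
        T = np.asarray(self.transform, dtype=float)
        if T.ndim == 0:
            if k != d_post:
                raise ValueError(
                    f"scalar transform requires matching dimensions "
                    f"({k} != {d_post})"
                )
            return float(T) * np.eye(d_post)
        T = np.atleast_2d(T)
        if T.shape != (d_post, k):
            raise ValueError(
                f"transform shape {T.shape} != expected ({d_post}, {k})"
            )
        return T


@dataclass(eq=False)
class ProbeSpec:
    """Request to record one attribute of one object during simulation."""

    target: Union[EnsembleSpec, NodeSpec]
    attribute: str
    filter_tau: Optional[float] = None
    sample_every: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        known = set().union(*PROBE_ATTRIBUTES.values())
        if self.attribute not in known:
            raise ValueError(
                f"unknown probe attribute {self.attribute!r}; "
                f"known attributes: {sorted(known)}"
            )
        # attribute/target-kind compatibility is reported by validate()


@dataclass(eq=False)
class NetworkSpec:
    """A reusable group of interconnected objects with named endpoints.

    ``inputs`` and ``outputs`` map exposed names to member objects (usually
    passthrough nodes) so callers can connect to the network without knowing
    its internals.  Networks nest to arbitrary depth; flattening a model
    recursively replaces networks with their core members.
    """

    name: Optional[str]
    members: list = field(default_factory=list)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def add(self, obj):
        self.members.append(obj)
        return obj


@dataclass(eq=False)
class ModelSpec:
    """Container for a complete model: the unit handed to the builder."""

    name: str = "model"
    objects: list = field(default_factory=list)
    seed: Optional[int] = None
    _counter: int = field(default=0, repr=False)

    def add(self, obj):
        return add_object(self, obj)

    def flattened(self):
        """Core (non-network) objects in depth-first insertion order."""
        return _flatten(self.objects)


def _kind(obj) -> str:
    if isinstance(obj, EnsembleSpec):
        return "ensemble"
    if isinstance(obj, NodeSpec):
        return "node"
    if isinstance(obj, ConnectionSpec):
        return "connection"
    if isinstance(obj, ProbeSpec):
        return "probe"
    if isinstance(obj, NetworkSpec):
        return "network"
    if isinstance(obj, NeuronView):
        return "neurons"
    raise TypeError(f"not a model object: {obj!r}")


def _flatten(objects) -> list:
    flat = []
    for obj in objects:
        if isinstance(obj, NetworkSpec):
            flat.extend(_flatten(obj.members))
        else:
            flat.append(obj)
    return flat


def add_object(model: ModelSpec, obj) -> ModelSpec:
    """Add a spec to the model, auto-naming unnamed objects.

    Duplicate names (over the flattened object list) are rejected so that
    signals, probes, and serialized configs stay unambiguous.
    """
    kind = _kind(obj)  # raises on non-spec input
    if getattr(obj, "name", None) is None:
        obj.name = f"{kind}{model._counter}"
    model._counter += 1
    existing = {o.name for o in model.flattened()}
    existing.update(o.name for o in model.objects if isinstance(o, NetworkSpec))
    new_names = (
        [o.name for o in _flatten([obj])] + [obj.name]
        if isinstance(obj, NetworkSpec)
        else [obj.name]
    )
    for nm in new_names:
        if nm in existing:
            raise ValueError(f"duplicate object name {nm!r} in model {model.name!r}")
    model.objects.append(obj)
    return model


def connect(
    pre,
    post,
    function=None,
    transform=None,
    filter_tau=DEFAULT_FILTER,
    weights=None,
    name=None,
) -> ConnectionSpec:
    """Create a validated connection from ``pre`` to ``post``.

    Dimension compatibility (after the optional decoded ``function`` and
    linear ``transform``) is checked immediately; the returned spec still
    needs to be added to a model.
    """
    return ConnectionSpec(
        pre=pre,
        post=post,
        function=function,
        transform=transform,
        filter_tau=filter_tau,
        weights=weights,
        name=name,
    )


def probe(
    target, attribute="decoded_output", filter_tau=None, sample_every=None, name=None
) -> ProbeSpec:
    """Create a validated probe of ``attribute`` on ``target``."""
    return ProbeSpec(
        target=target,
        attribute=attribute,
        filter_tau=filter_tau,
        sample_every=sample_every,
        name=name,
    )


def _underlying(obj):
    return obj.ensemble if isinstance(obj, NeuronView) else obj


def validate(model: ModelSpec) -> list:
    """Check all model-level invariants; returns violations, raises nothing.

    An empty list means the model is buildable: names unique, connection
    endpoints and probe targets are members, probe attributes match target
    kinds, encoder rows have unit norm, and transforms are shape-consistent.
    """
    violations = []
    flat = model.flattened()
    members = {id(o) for o in flat}

    names = [o.name for o in flat]
    for nm in sorted({n for n in names if names.count(n) > 1}):
        violations.append(f"duplicate object name {nm!r}")

    for obj in flat:
        kind = _kind(obj)
        if kind == "ensemble" and obj.encoders is not None:
            norms = np.linalg.norm(obj.encoders, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                violations.append(
                    f"ensemble {obj.name!r}: encoder rows are not unit vectors"
                )
        elif kind == "connection":
            for end, label in ((obj.pre, "pre"), (obj.post, "post")):
                target = _underlying(end)
                if id(target) not in members:
                    violations.append(
                        f"connection {obj.name!r}: {label} object "
                        f"{getattr(target, 'name', target)!r} is not in the model"
                    )
            if obj.function is not None and not isinstance(obj.pre, EnsembleSpec):
                violations.append(
                    f"connection {obj.name!r}: decoded function on a "
                    "non-ensemble source"
                )
        elif kind == "probe":
            if id(obj.target) not in members:
                violations.append(
                    f"probe {obj.name!r}: target "
                    f"{getattr(obj.target, 'name', obj.target)!r} is not in the model"
                )
            valid = PROBE_ATTRIBUTES.get(_kind(obj.target), set())
            if obj.attribute not in valid:
                violations.append(
                    f"probe {obj.name!r}: attribute {obj.attribute!r} is invalid "
                    f"for a {_kind(obj.target)}"
                )
    return violations
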