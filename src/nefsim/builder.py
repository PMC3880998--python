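"""Compile a symbolic model into signals and operators.

The builder fills in every detail the symbolic layer leaves unspecified —
encoders, gains and biases, decoders — using per-object random streams
derived from the model seed and each object's insertion index, so builds
are reproducible regardless of when or where objects were constructed.
Each ensemble becomes a cluster of signals (input, bias and input currents,
membrane voltage, refractory clocks, spikes) tied together by encode,
neuron-update, decode, filter and transform operators; the operator list is
then dependency-sorted into an executable schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import model as m
from .decoders import (
    DecoderSolveProblem,
    default_n_eval_points,
    sample_eval_points,
    solve_decoders,
)
from .neurons import gain_bias, sample_encoders, tuning_curves
from .operators import (
    Copy,
    DotInc,
    Lowpass,
    Reset,
    SimLIF,
    SimNode,
    Signal,
    schedule,
)
from .simulator import ExecutablePlan, ProbeHandle

__all__ = ["build", "BuildError", "ResolvedEnsemble", "BuiltConnection"]

DEFAULT_DT = 0.001

#: Cortical pyramidal-cell style defaults for unspecified tuning parameters.
DEFAULT_MAX_RATES = (200.0, 400.0)
DEFAULT_INTERCEPTS = (-1.0, 1.0)


class BuildError(ValueError):
    """A model spec could not be resolved into an executable plan."""


@dataclass
class ResolvedEnsemble:
    """An ensemble with all tuning parameters filled in."""

    spec: m.EnsembleSpec
    encoders: np.ndarray
    gain: np.ndarray
    bias: np.ndarray
    max_rates: np.ndarray
    intercepts: np.ndarray

    @property
    def neurons(self):
        return self.spec.neurons

    @property
    def radius(self) -> float:
        return self.spec.radius


@dataclass
class BuiltConnection:
    """Resolved data for one connection (decoders are None for non-decoded)."""

    spec: m.ConnectionSpec
    decoders: Optional[np.ndarray]
    transform: Optional[np.ndarray]
    weights: Optional[np.ndarray] = None


def _entropy(seed) -> int:
    return int(seed) & 0x7FFFFFFF


def _object_rng(model_seed: int, index: int, obj_seed=None,
                stream: int = 0) -> np.random.Generator:
    """Per-object stream: hierarchical hash of (model seed, insertion index).

    ``stream`` separates independent draws tied to the same object (e.g. an
    ensemble's tuning resolution vs its shared identity decoders).
    """
    if obj_seed is not None:
        ss = np.random.SeedSequence([_entropy(obj_seed), stream])
    else:
        ss = np.random.SeedSequence([_entropy(model_seed), index, stream])
    return np.random.default_rng(ss)


def _resolve_interval(value, default, n, rng):
    """Resolve an interval tuple / explicit array / None into n values."""
    if value is None:
        value = default
    if isinstance(value, tuple) and len(value) == 2:
        return rng.uniform(value[0], value[1], size=n)
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
    return arr


def resolve_ensemble(ens: m.EnsembleSpec, rng) -> ResolvedEnsemble:
    """Fill in encoders/max_rates/intercepts and solve gains and biases."""
    n, d = ens.neurons.n_neurons, ens.dimensions
    encoders = ens.encoders if ens.encoders is not None else sample_encoders(n, d, rng)
    max_rates = _resolve_interval(ens.max_rates, DEFAULT_MAX_RATES, n, rng)
    intercepts = _resolve_interval(ens.intercepts, DEFAULT_INTERCEPTS, n, rng)
    try:
        gain, bias = gain_bias(max_rates, intercepts, ens.neurons)
    except ValueError as e:
        raise BuildError(f"ensemble {ens.name!r}: {e}") from e
    return ResolvedEnsemble(ens, encoders, gain, bias, max_rates, intercepts)


def _solve_connection_decoders(
    resolved: ResolvedEnsemble, function, size_mid: int, rng
) -> np.ndarray:
    """Least-squares decoders for the (function of the) represented value."""
    ens = resolved.spec
    points = sample_eval_points(
        default_n_eval_points(ens.dimensions), ens.dimensions, rng
    ) * ens.radius
    activities = tuning_curves(resolved, points)
    if function is None:
        targets = points
    else:
        targets = np.empty((points.shape[0], size_mid))
        for i, x in enumerate(points):
            targets[i] = np.atleast_1d(np.asarray(function(x), dtype=float))
    return solve_decoders(DecoderSolveProblem(activities, targets))


class _Builder:
    def __init__(self, model: m.ModelSpec, dt: float, seed):
        self.model = model
        self.dt = dt
        mseed = model.seed if model.seed is not None else (seed or 0)
        self.model_seed = mseed
        self.signals: list = []
        self.operators: list = []
        self.ensembles: dict = {}       # EnsembleSpec -> ResolvedEnsemble
        self.connections: dict = {}     # ConnectionSpec -> BuiltConnection
        self.sig: dict = {}             # (id(obj), role) -> Signal
        self.probes: list = []
        self.ens_index: dict = {}       # EnsembleSpec -> insertion index
        self._identity_decoders: dict = {}

    def signal(self, name, initial, kind="stepwise") -> Signal:
        s = Signal(name, np.array(initial, dtype=float), kind=kind)
        self.signals.append(s)
        return s

    def add_op(self, op):
        self.operators.append(op)
        return op

    # -- object builders ---------------------------------------------------

    def build_ensemble(self, ens: m.EnsembleSpec, index: int):
        self.ens_index[ens] = index
        rng = _object_rng(self.model_seed, index, ens.seed)
        resolved = resolve_ensemble(ens, rng)
        self.ensembles[ens] = resolved
        n, d = ens.neurons.n_neurons, ens.dimensions
        nm = ens.name
        sin = self.signal(f"{nm}.in", np.zeros(d))
        bias = self.signal(f"{nm}.bias", resolved.bias, kind="constant")
        J = self.signal(f"{nm}.J", np.zeros(n))
        voltage = self.signal(f"{nm}.voltage", np.zeros(n), kind="state")
        refractory = self.signal(f"{nm}.refractory", np.zeros(n), kind="state")
        spikes = self.signal(f"{nm}.spikes", np.zeros(n))
        scaled_enc = self.signal(
            f"{nm}.scaled_encoders",
            resolved.gain[:, None] * resolved.encoders / ens.radius,
            kind="constant",
        )
        self.sig.update({
            (id(ens), "in"): sin,
            (id(ens), "J"): J,
            (id(ens), "voltage"): voltage,
            (id(ens), "refractory"): refractory,
            (id(ens), "spikes"): spikes,
        })
        self.add_op(Reset(sin, 0.0))
        self.add_op(Copy(J, bias))
        self.add_op(DotInc(scaled_enc, sin, J, tag=f"dotinc:encode:{nm}"))
        self.add_op(SimLIF(J, spikes, voltage, refractory, ens.neurons))

    def build_node(self, node: m.NodeSpec, index: int):
        nm = node.name
        out = self.signal(f"{nm}.out", np.zeros(node.size_out))
        self.sig[(id(node), "out")] = out
        nin = None
        if node.size_in > 0:
            nin = self.signal(f"{nm}.in", np.zeros(node.size_in))
            self.sig[(id(node), "in")] = nin
            self.add_op(Reset(nin, 0.0))
        if node.output is None or callable(node.output):
            self.add_op(SimNode(out, node.output if callable(node.output) else None,
                                input_sig=nin, size_out=node.size_out, name=nm))
        else:
            self.add_op(Reset(out, np.asarray(node.output, dtype=float),
                              tag=f"reset:const:{nm}"))

    def _source_signal(self, conn: m.ConnectionSpec, index: int):
        """Signal carrying the connection's pre-transform value, plus filtering."""
        pre, nm, tau = conn.pre, conn.name, conn.filter_tau
        if isinstance(pre, m.EnsembleSpec):
            resolved = self.ensembles[pre]
            rng = _object_rng(self.model_seed, index, conn.seed)
            try:
                D = _solve_connection_decoders(resolved, conn.function,
                                               conn.size_mid, rng)
            except ValueError as e:
                raise BuildError(f"connection {nm!r} from {pre.name!r}: {e}") from e
            self.connections[conn] = BuiltConnection(conn, D, conn.transform)
            DT = self.signal(f"{nm}.decoders", D.T, kind="constant")
            decoded = self.signal(f"{nm}.decoded", np.zeros(D.shape[1]))
            self.add_op(Reset(decoded, 0.0))
            self.add_op(DotInc(DT, self.sig[(id(pre), "spikes")], decoded,
                               tag=f"dotinc:decode:{nm}"))
            raw = decoded
        elif isinstance(pre, m.NodeSpec):
            self.connections[conn] = BuiltConnection(conn, None, conn.transform)
            raw = self.sig[(id(pre), "out")]
        else:  # NeuronView source
            spikes = self.sig[(id(pre.ensemble), "spikes")]
            if conn.weights is not None:
                self.connections[conn] = BuiltConnection(
                    conn, None, None, weights=conn.weights)
                W = self.signal(f"{nm}.weights", conn.weights, kind="constant")
                raw = self.signal(f"{nm}.wsum", np.zeros(conn.weights.shape[0]))
                self.add_op(Reset(raw, 0.0))
                self.add_op(DotInc(W, spikes, raw, tag=f"dotinc:weights:{nm}"))
            else:
                self.connections[conn] = BuiltConnection(conn, None, conn.transform)
                raw = spikes
        if tau:
            filtered = self.signal(f"{nm}.filtered", np.zeros(raw.shape),
                                   kind="state")
            self.add_op(Lowpass(filtered, raw, tau))
            return filtered
        return raw

    def _target_signal(self, conn: m.ConnectionSpec) -> Signal:
        post = conn.post
        if isinstance(post, m.EnsembleSpec):
            return self.sig[(id(post), "in")]
        if isinstance(post, m.NodeSpec):
            key = (id(post), "in")
            if key not in self.sig:
                raise BuildError(
                    f"connection {conn.name!r}: node {post.name!r} has size_in=0"
                )
            return self.sig[key]
        return self.sig[(id(post.ensemble), "J")]  # neuron-level drive

    def build_connection(self, conn: m.ConnectionSpec, index: int):
        src = self._source_signal(conn, index)
        dst = self._target_signal(conn)
        nm = conn.name
        if conn.weights is not None:
            eye = self.signal(f"{nm}.eye", np.eye(src.shape[0]), kind="constant")
            self.add_op(DotInc(eye, src, dst, tag=f"dotinc:inject:{nm}"))
        else:
            T = self.signal(f"{nm}.transform", conn.transform, kind="constant")
            self.add_op(DotInc(T, src, dst, tag=f"dotinc:transform:{nm}"))

    def identity_decoders(self, ens: m.EnsembleSpec) -> np.ndarray:
        """Identity-function decoders, shared by every probe of an ensemble."""
        if ens not in self._identity_decoders:
            rng = _object_rng(self.model_seed, self.ens_index[ens],
                              ens.seed, stream=1)
            self._identity_decoders[ens] = _solve_connection_decoders(
                self.ensembles[ens], None, ens.dimensions, rng)
        return self._identity_decoders[ens]

    def build_probe(self, pr: m.ProbeSpec, index: int):
        nm, target = pr.name, pr.target
        if pr.attribute == "decoded_output":
            try:
                D = self.identity_decoders(target)
            except ValueError as e:
                raise BuildError(f"probe {nm!r} on {target.name!r}: {e}") from e
            DT = self.signal(f"{nm}.decoders", D.T, kind="constant")
            raw = self.signal(f"{nm}.decoded", np.zeros(target.dimensions))
            self.add_op(Reset(raw, 0.0))
            self.add_op(DotInc(DT, self.sig[(id(target), "spikes")], raw,
                               tag=f"dotinc:probe:{nm}"))
        elif pr.attribute == "node_output":
            raw = self.sig[(id(target), "out")]
        else:  # spikes, voltage, input_current
            role = {"spikes": "spikes", "voltage": "voltage",
                    "input_current": "J"}[pr.attribute]
            raw = self.sig[(id(target), role)]
        if pr.filter_tau:
            filtered = self.signal(f"{nm}.filtered", np.zeros(raw.shape),
                                   kind="state")
            self.add_op(Lowpass(filtered, raw, pr.filter_tau))
            raw = filtered
        every = 1 if pr.sample_every is None else max(
            1, int(round(pr.sample_every / self.dt)))
        self.probes.append(ProbeHandle(pr, raw, every))

    # -- top level ---------------------------------------------------------

    def build(self) -> ExecutablePlan:
        flat = self.model.flattened()
        ensembles = [(i, o) for i, o in enumerate(flat)
                     if isinstance(o, m.EnsembleSpec)]
        nodes = [(i, o) for i, o in enumerate(flat) if isinstance(o, m.NodeSpec)]
        conns = [(i, o) for i, o in enumerate(flat)
                 if isinstance(o, m.ConnectionSpec)]
        probes = [(i, o) for i, o in enumerate(flat) if isinstance(o, m.ProbeSpec)]

        for i, ens in ensembles:
            self.build_ensemble(ens, i)
        for i, node in nodes:
            self.build_node(node, i)
        for i, conn in conns:
            self.build_connection(conn, i)
        for i, pr in probes:
            self.build_probe(pr, i)

        ordered = schedule(self.operators)
        plan = ExecutablePlan(
            signals=self.signals,
            operators=ordered,
            dt=self.dt,
            probes=self.probes,
            ensembles=self.ensembles,
            connections=self.connections,
        )
        return plan


def build(model: m.ModelSpec, dt: float = DEFAULT_DT, seed=None) -> ExecutablePlan:
    """Compile ``model`` into an executable plan.

    ``seed`` feeds every random resolution (encoders, tuning parameters,
    evaluation points); an explicit ``model.seed`` takes precedence, and
    per-object seeds override both.  The model itself is never mutated, so
    it can be built again with different settings.

    Raises :class:`BuildError` when the spec cannot be resolved (invalid
    model per :func:`nefsim.model.validate`, unreachable firing rates,
    silent-neuron decoder solves) and :class:`~nefsim.operators.SchedulingError`
    for same-step dependency cycles such as unfiltered recurrences.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    violations = m.validate(model)
    if violations:
        raise BuildError(
            f"model {model.name!r} is invalid:\n  " + "\n  ".join(violations)
        )
    return _Builder(model, dt, seed).build()
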