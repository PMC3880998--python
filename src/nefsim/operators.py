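"""Signals, operators, and the dependency-sorted schedule.

The builder reduces a symbolic model to a flat computation graph: *signals*
are named value buffers and *operators* are the computations applied to
them each timestep.  Scheduling is a topological sort under the per-signal
discipline

    set  <  inc  <  read  <  update

so that within a step every full write happens before increments, all
writes/increments before reads, and state commits (updates) last — reads of
a state signal therefore always see the previous step's value, which is
what makes recurrent (filtered) connections well defined.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Signal",
    "Operator",
    "Reset",
    "Copy",
    "DotInc",
    "SimLIF",
    "Lowpass",
    "SimNode",
    "SchedulingError",
    "schedule",
    "lowpass_step",
]


@dataclass(eq=False)
class Signal:
    """A named value buffer used by the simulator.

    ``kind`` is ``constant`` (written once at build), ``stepwise``
    (recomputed from scratch every step), or ``state`` (persists across
    steps, modified only by update operators).
    """

    name: str
    initial: np.ndarray
    kind: str = "stepwise"

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        if self.kind not in ("constant", "stepwise", "state"):
            raise ValueError(f"unknown signal kind {self.kind!r}")

    @property
    def shape(self):
        return self.initial.shape

    def __repr__(self) -> str:  # pragma: no cover
        return f"Signal({self.name!r}, shape={self.initial.shape}, kind={self.kind})"


class SchedulingError(ValueError):
    """Raised when operators cannot be ordered (same-step read/write cycle)."""


@dataclass(eq=False)
class Operator:
    """Base per-timestep computation with declared signal access sets."""

    tag: str = ""
    reads: list = field(default_factory=list)
    sets: list = field(default_factory=list)
    incs: list = field(default_factory=list)
    updates: list = field(default_factory=list)

    def make_step(self, values, plan):
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.tag})"


class Reset(Operator):
    """Set a signal to a constant value at the start of each step."""

    def __init__(self, dst: Signal, value: float = 0.0, tag: str = ""):
        super().__init__(tag=tag or f"reset:{dst.name}", sets=[dst])
        self.dst, self.value = dst, value

    def make_step(self, values, plan):
        dst, value = values[self.dst], self.value

        def step():
            dst[...] = value

        return step


class Copy(Operator):
    """Overwrite ``dst`` with ``src`` each step."""

    def __init__(self, dst: Signal, src: Signal, tag: str = ""):
        super().__init__(tag=tag or f"copy:{src.name}->{dst.name}",
                         sets=[dst], reads=[src])
        self.dst, self.src = dst, src

    def make_step(self, values, plan):
        dst, src = values[self.dst], values[self.src]

        def step():
            dst[...] = src

        return step


class DotInc(Operator):
    """Increment ``Y += A @ X`` (A is typically a constant matrix)."""

    def __init__(self, A: Signal, X: Signal, Y: Signal, tag: str = ""):
        super().__init__(tag=tag or f"dotinc:{A.name}*{X.name}->{Y.name}",
                         reads=[A, X], incs=[Y])
        self.A, self.X, self.Y = A, X, Y

    def make_step(self, values, plan):
        A, X, Y = values[self.A], values[self.X], values[self.Y]

        def step():
            np.add(Y, A @ X, out=Y)

        return step


class SimLIF(Operator):
    """Advance LIF membranes one step: read currents, emit spikes.

    Spikes are area-1 impulses (value 1/dt on the spike step) so that a
    lowpass-filtered spike train has firing-rate units; voltage and
    refractory clocks are state updates committed this step.
    """

    def __init__(self, J: Signal, spikes: Signal, voltage: Signal,
                 refractory: Signal, params, tag: str = ""):
        super().__init__(tag=tag or f"simlif:{spikes.name}",
                         reads=[J], sets=[spikes], updates=[voltage, refractory])
        self.J, self.spikes = J, spikes
        self.voltage, self.refractory = voltage, refractory
        self.params = params

    def make_step(self, values, plan):
        from .neurons import LIFState, lif_step

        J, out = values[self.J], values[self.spikes]
        state = LIFState(values[self.voltage], values[self.refractory])
        params, dt = self.params, plan.dt

        def step():
            _, spikes = lif_step(state, J, dt, params)
            out[...] = spikes

        return step


class Lowpass(Operator):
    """First-order synaptic filter: state update of ``dst`` from ``src``."""

    def __init__(self, dst: Signal, src: Signal, tau: float, tag: str = ""):
        super().__init__(tag=tag or f"lowpass:{src.name}->{dst.name}",
                         reads=[src], updates=[dst])
        self.dst, self.src, self.tau = dst, src, tau

    def make_step(self, values, plan):
        dst, src = values[self.dst], values[self.src]
        if not self.tau:
            def step():
                dst[...] = src
            return step
        decay = np.exp(-plan.dt / self.tau)

        def step():
            np.multiply(dst, decay, out=dst)
            np.add(dst, (1.0 - decay) * src, out=dst)

        return step


class SimNode(Operator):
    """Evaluate a node function (or passthrough) and set its output signal."""

    def __init__(self, output_sig: Signal, fn, input_sig: Optional[Signal] = None,
                 size_out: int = 0, name: str = "", tag: str = ""):
        reads = [input_sig] if input_sig is not None else []
        super().__init__(tag=tag or f"simnode:{output_sig.name}",
                         reads=reads, sets=[output_sig])
        self.output_sig, self.fn, self.input_sig = output_sig, fn, input_sig
        self.size_out, self.name = size_out, name

    def make_step(self, values, plan):
        out = values[self.output_sig]
        inp = values[self.input_sig] if self.input_sig is not None else None

        if self.fn is None:  # passthrough
            def step():
                out[...] = inp
            return step

        fn, size_out, name = self.fn, self.size_out, self.name

        def step():
            result = fn(plan.node_time) if inp is None else fn(plan.node_time, inp)
            result = np.atleast_1d(np.asarray(result, dtype=float))
            if result.size != size_out:
                raise RuntimeError(
                    f"node {name!r} returned {result.size} values "
                    f"(expected {size_out}) at step {plan.steps}"
                )
            out[...] = result

        return step


def lowpass_step(y, x, dt: float, tau) -> np.ndarray:
    """One first-order lowpass update: ``y' = y e^(-dt/tau) + x (1 - e^(-dt/tau))``.

    ``tau`` of 0 or None means a passthrough (``y' = x``).
    """
    x = np.asarray(x, dtype=float)
    if not tau:
        return x.copy()
    decay = np.exp(-dt / tau)
    return np.asarray(y, dtype=float) * decay + x * (1.0 - decay)


def schedule(operators) -> list:
    """Order operators so every signal's set < inc < read < update.

    The order is a deterministic topological sort with ties broken by
    operator tag, so it is invariant to the insertion order of the operator
    list.  Raises :class:`SchedulingError` listing the cycle when a
    same-step read/write cycle exists (e.g. an unfiltered recurrent loop),
    and on signals with more than one setter.
    """
    setters: dict = {}
    incers: dict = {}
    readers: dict = {}
    updaters: dict = {}
    for op in operators:
        for sig in op.sets:
            if sig in setters:
                raise SchedulingError(
                    f"signal {sig.name!r} has multiple setters: "
                    f"{setters[sig]!r} and {op!r}"
                )
            setters[sig] = op
        for sig in op.incs:
            incers.setdefault(sig, []).append(op)
        for sig in op.reads:
            readers.setdefault(sig, []).append(op)
        for sig in op.updates:
            updaters.setdefault(sig, []).append(op)

    successors: dict = {op: set() for op in operators}
    indegree = {op: 0 for op in operators}

    def add_edge(a, b):
        if a is not b and b not in successors[a]:
            successors[a].add(b)
            indegree[b] += 1

    signals = set(setters) | set(incers) | set(readers) | set(updaters)
    for sig in signals:
        stages = (
            [setters[sig]] if sig in setters else [],
            incers.get(sig, []),
            readers.get(sig, []),
            updaters.get(sig, []),
        )
        for i, earlier in enumerate(stages):
            for later_stage in stages[i + 1:]:
                for a in earlier:
                    for b in later_stage:
                        add_edge(a, b)

    order_index = {op: i for i, op in enumerate(operators)}
    ready = [(op.tag, order_index[op], op) for op in operators if indegree[op] == 0]
    heapq.heapify(ready)
    ordered = []
    while ready:
        _, _, op = heapq.heappop(ready)
        ordered.append(op)
        for succ in sorted(successors[op], key=lambda o: o.tag):
            indegree[succ] -= 1
            if indegree[succ] == 0:
                heapq.heappush(ready, (succ.tag, order_index[succ], succ))
    if len(ordered) < len(operators):
        stuck = [op for op in operators if op not in set(ordered)]
        raise SchedulingError(
            "same-step dependency cycle among operators: "
            + ", ".join(repr(op) for op in stuck)
        )
    return ordered
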