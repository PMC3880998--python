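"""The reference time-stepping engine and probe recording.

An :class:`ExecutablePlan` owns all simulation state (one value buffer per
signal), so independent plans never interfere.  Each call to
:meth:`ExecutablePlan.run` advances the simulation — state persists, so two
half-second runs are identical to one one-second run — and returns the
accumulated probe records.  Probe CSV output uses 17 significant digits so
identical runs are byte-identical on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["ProbeRecord", "ProbeHandle", "ExecutablePlan", "run", "write_probe_csv"]


@dataclass
class ProbeRecord:
    """Time-indexed matrix of sampled signal values."""

    name: str
    times: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ProbeHandle:
    """Internal binding of a probe spec to its source signal."""

    spec: object
    signal: object
    every: int = 1
    times: list = field(default_factory=list)
    samples: list = field(default_factory=list)


class ExecutablePlan:
    """A compiled model: signals, a dependency-sorted schedule, and state."""

    def __init__(self, signals, operators, dt, probes, ensembles=None,
                 connections=None):
        self.signals = signals
        self.operators = operators
        self.dt = dt
        self.probes = probes
        self.ensembles = ensembles or {}
        self.connections = connections or {}
        self.steps = 0
        self.node_time = 0.0
        self.values = {s: s.initial.copy() for s in signals}
        self._steppers = [op.make_step(self.values, self) for op in operators]

    @property
    def time(self) -> float:
        """Current simulated time in seconds."""
        return self.steps * self.dt

    def signal_value(self, name: str) -> np.ndarray:
        """Current value of a signal by name (for inspection/testing)."""
        for s in self.signals:
            if s.name == name:
                return self.values[s]
        raise KeyError(name)

    def step(self) -> None:
        """Advance the simulation by one timestep."""
        # nodes see the time at the end of the step being computed
        self.node_time = (self.steps + 1) * self.dt
        for stepper in self._steppers:
            stepper()
        self.steps += 1
        for handle in self.probes:
            if self.steps % handle.every == 0:
                handle.times.append(self.steps * self.dt)
                handle.samples.append(self.values[handle.signal].copy())

    def run(self, duration: float) -> dict:
        """Run for ``duration`` seconds; returns {probe spec: ProbeRecord}.

        Probe records accumulate across calls, so the returned records
        always cover the full simulation so far.
        """
        if duration <= 0:
            raise ValueError(f"duration must be positive, got {duration}")
        n_steps = int(round(duration / self.dt))
        for _ in range(n_steps):
            self.step()
        return self.data()

    def data(self) -> dict:
        """Probe records collected so far, keyed by probe spec."""
        out = {}
        for handle in self.probes:
            values = (np.array(handle.samples) if handle.samples
                      else np.empty((0,) + handle.signal.shape))
            out[handle.spec] = ProbeRecord(
                handle.spec.name, np.array(handle.times), values
            )
        return out


def run(plan: ExecutablePlan, duration: float) -> dict:
    """Functional alias for :meth:`ExecutablePlan.run`."""
    return plan.run(duration)


def write_probe_csv(record: ProbeRecord, path) -> None:
    """Write a probe record as CSV: header ``time,<name>[i],...``.

    Numbers are formatted with 17 significant digits, enough to round-trip
    IEEE doubles, so identical simulations produce byte-identical files.
    """
    values = np.atleast_2d(record.values)
    ncols = values.shape[1] if len(record) else int(np.prod(record.values.shape[1:]))
    header = "time," + ",".join(f"{record.name}[{i}]" for i in range(ncols))
    with open(path, "w", newline="") as f:
        f.write(header + "\n")
        for t, row in zip(record.times, values):
            f.write(f"{t:.17g}," + ",".join(f"{v:.17g}" for v in np.ravel(row)))
            f.write("\n")


def read_probe_csv(path) -> ProbeRecord:
    """Read a probe CSV written by :func:`write_probe_csv`."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    with open(path) as f:
        header = f.readline().strip().split(",")
    name = header[1].rsplit("[", 1)[0] if len(header) > 1 else "probe"
    return ProbeRecord(name, data[:, 0], data[:, 1:])
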