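"""Leaky integrate-and-fire dynamics, rate curves, and gain/bias solving.

A LIF neuron driven by input current ``J`` (in threshold units: a constant
current of 1 holds the membrane exactly at threshold) fires at the analytic
rate

    a(J) = 1 / (tau_ref + tau_rc * ln(1 + 1 / (J - 1)))     for J > 1,

and is silent otherwise.  An ensemble maps a represented vector ``x`` to
per-neuron currents ``J_i = gain_i * (e_i . x / radius) + bias_i`` where
``e_i`` is the neuron's encoder (preferred direction).  ``gain_bias`` inverts
the rate curve so each neuron starts firing exactly at its intercept and
reaches its maximum rate at the edge of the represented range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LIFParams",
    "LIFState",
    "lif_rate",
    "gain_bias",
    "lif_step",
    "sample_encoders",
    "tuning_curves",
]


@dataclass(frozen=True)
class LIFParams:
    """Symbolic LIF neuron description.

    Parameters
    ----------
    n_neurons : int
        Number of neurons in the population.
    tau_rc : float
        Membrane RC time constant in seconds.
    tau_ref : float
        Absolute refractory period in seconds.
    """

    n_neurons: int
    tau_rc: float = 0.02
    tau_ref: float = 0.002

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError(f"n_neurons must be >= 1, got {self.n_neurons}")
        if self.tau_rc <= 0:
            raise ValueError(f"tau_rc must be positive, got {self.tau_rc}")
        if self.tau_ref < 0:
            raise ValueError(f"tau_ref must be non-negative, got {self.tau_ref}")

    @property
    def max_possible_rate(self) -> float:
        """Firing-rate ceiling 1/tau_ref imposed by the refractory period."""
        return np.inf if self.tau_ref == 0 else 1.0 / self.tau_ref


@dataclass
class LIFState:
    """Mutable per-neuron simulation state.

    ``voltage`` is the normalized membrane potential (threshold at 1, reset
    at 0); ``refractory_time`` is the remaining refractory clock in seconds.
    """

    voltage: np.ndarray
    refractory_time: np.ndarray

    @classmethod
    def zeros(cls, n_neurons: int) -> "LIFState":
        return cls(np.zeros(n_neurons), np.zeros(n_neurons))


def lif_rate(J, params: LIFParams):
    """Analytic steady-state firing rate (Hz) for constant current ``J``.

    Vectorized over ``J``; subthreshold currents (J <= 1) give 0 Hz.
    """
    J = np.asarray(J, dtype=float)
    out = np.zeros_like(J)
    above = J > 1
    Ja = J[above]
    out[above] = 1.0 / (params.tau_ref + params.tau_rc * np.log1p(1.0 / (Ja - 1.0)))
    return out if out.ndim else float(out)


def gain_bias(max_rate, intercept, params: LIFParams):
    """Solve for (gain, bias) hitting a max rate at x=1 and threshold at x=intercept.

    With J(x) = gain*x + bias along the neuron's encoder, the returned pair
    satisfies J(intercept) = 1 (rate exactly zero, about to rise) and
    lif_rate(J(1)) = max_rate.  Closed form: invert the rate curve at x = 1,

        J_max = 1 / (1 - exp((tau_ref - 1/max_rate) / tau_rc)),

    then fit the affine current map through the two constraint points.

    Parameters may be scalars or arrays (broadcast together).  Raises
    ``ValueError`` if any requested rate is at or above the 1/tau_ref ceiling,
    or any intercept is >= 1.
    """
    max_rate = np.asarray(max_rate, dtype=float)
    intercept = np.asarray(intercept, dtype=float)
    if np.any(max_rate <= 0):
        raise ValueError("max_rate must be positive")
    if np.any(max_rate >= params.max_possible_rate):
        raise ValueError(
            f"max_rate must be below the refractory ceiling "
            f"1/tau_ref = {params.max_possible_rate:g} Hz"
        )
    if np.any(intercept >= 1):
        raise ValueError("intercept must be < 1")
    J_max = 1.0 / (1.0 - np.exp((params.tau_ref - 1.0 / max_rate) / params.tau_rc))
    gain = (1.0 - J_max) / (intercept - 1.0)
    bias = 1.0 - gain * intercept
    return gain, bias


def lif_step(state: LIFState, J, dt: float, params: LIFParams):
    """Advance LIF membrane dynamics by one timestep.

    Exact exponential integration toward the drive current:
    ``V <- J + (V - J) * exp(-delta/tau_rc)`` where ``delta`` is the part of
    the step outside the refractory window (fractional-step refractory
    handling).  Neurons crossing threshold emit an area-1 impulse (value
    ``1/dt`` for this step), reset to 0, and enter the refractory period
    starting from the interpolated spike time within the step.

    Returns ``(state, spikes)``; ``state`` is updated in place and returned
    for convenience.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    J = np.asarray(J, dtype=float)
    V = state.voltage
    ref = state.refractory_time

    # integrate only the non-refractory part of the step
    delta = np.clip(dt - ref, 0.0, dt)
    V[...] = J + (V - J) * np.exp(-delta / params.tau_rc)
    ref[...] = np.maximum(ref - dt, 0.0)

    spiked = V > 1.0
    spikes = np.zeros_like(V)
    spikes[spiked] = 1.0 / dt

    if np.any(spiked):
        # interpolate the threshold-crossing time inside the step so the
        # refractory window starts when the spike actually happened
        Js, Vs = J[spiked], V[spiked]
        t_left = params.tau_rc * np.log1p(-(Vs - 1.0) / (Js - 1.0))
        ref[spiked] = params.tau_ref + t_left
        V[spiked] = 0.0
    np.clip(V, 0.0, None, out=V)
    return state, spikes


def sample_encoders(n: int, d: int, rng) -> np.ndarray:
    """Draw ``n`` encoders uniformly from the unit hypersphere in ``d`` dims.

    ``rng`` is a seed or ``numpy.random.Generator``.  Gaussian draws
    normalized to unit length give the uniform spherical distribution.
    """
    if n < 1 or d < 1:
        raise ValueError("n and d must be >= 1")
    rng = np.random.default_rng(rng)
    enc = rng.standard_normal((n, d))
    norms = np.linalg.norm(enc, axis=1, keepdims=True)
    # resample the (measure-zero) degenerate rows
    while np.any(norms == 0):  # pragma: no cover
        bad = norms[:, 0] == 0
        enc[bad] = rng.standard_normal((bad.sum(), d))
        norms = np.linalg.norm(enc, axis=1, keepdims=True)
    return enc / norms


def tuning_curves(ens, inputs: np.ndarray) -> np.ndarray:
    """Rate responses (Hz) of a resolved ensemble at each input vector.

    ``ens`` must expose ``encoders [n x d]``, ``gain [n]``, ``bias [n]``,
    ``radius`` and ``neurons`` (LIFParams).  ``inputs`` is ``[m x d]`` in
    represented (unscaled) units; entry ``(i, j)`` of the result is neuron
    ``j``'s rate at input ``x_i``.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    proj = inputs @ ens.encoders.T / ens.radius
    J = ens.gain * proj + ens.bias
    return lif_rate(J, ens.neurons)
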