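"""Executable example models: communication channel, Lorenz attractor,
circular convolution, plus a neural oscillator and integrator.

Each ``*_model`` function returns an :class:`ExampleModel` bundling the
symbolic model, its named probes, run metadata for manifests, and a default
duration.  These are the standard demonstrations of the three NEF
principles: routing represented values unchanged (representation and
transformation), attractor dynamics from recurrent decoded functions
(dynamics), and vector binding through networks of product ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import EnsembleSpec, ModelSpec, NodeSpec, ProbeSpec, connect, probe
from .networks import (
    circular_convolution_network,
    circular_convolution_oracle,
    nonlinear_feedback,
    integrator,
    oscillator,
)
from .neurons import LIFParams

__all__ = [
    "NoiseSpec",
    "LorenzParams",
    "ExampleModel",
    "bandlimited_noise",
    "sampled_signal_node",
    "communication_channel_model",
    "lorenz_model",
    "circconv_model",
    "oscillator_model",
    "integrator_model",
]


@dataclass
class NoiseSpec:
    """Band-limited Gaussian white-noise stimulus parameters."""

    duration: float = 1.0
    dt: float = 0.001
    limit: float = 5.0      # cutoff frequency, Hz
    rms: float = 0.5        # target root-mean-square amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.dt)
        if self.limit >= nyquist:
            raise ValueError(
                f"limit {self.limit} Hz must be below the Nyquist frequency "
                f"{nyquist} Hz"
            )
        if self.rms <= 0:
            raise ValueError("rms must be positive")


@dataclass
class LorenzParams:
    """Classic chaotic-attractor coefficients plus neural parameters.

    The attractor is represented in shifted coordinates (third state
    ``z' = z - rho``) so it is centred near the origin and fits inside the
    ensemble's represented ball of the given radius.
    """

    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    tau: float = 0.1
    n_neurons: int = 2000
    radius: float = 60.0


@dataclass
class ExampleModel:
    """A ready-to-build example: model, named probes, and manifest metadata."""

    model: ModelSpec
    probes: dict
    meta: dict = field(default_factory=dict)
    default_duration: float = 1.0


def bandlimited_noise(spec: NoiseSpec) -> np.ndarray:
    """Gaussian white noise with spectral support limited to [0, limit] Hz.

    Built in the frequency domain — independent Gaussian coefficients for
    components at or below the cutoff, zero above — inverse-transformed and
    rescaled to the target rms.  Deterministic given the seed.
    """
    steps = int(round(spec.duration / spec.dt))
    rng = np.random.default_rng(spec.seed)
    freqs = np.fft.rfftfreq(steps, spec.dt)
    coeffs = np.zeros(freqs.size, dtype=complex)
    band = freqs <= spec.limit
    nb = int(band.sum())
    coeffs[band] = rng.standard_normal(nb) + 1j * rng.standard_normal(nb)
    coeffs[0] = coeffs[0].real  # DC must be real
    signal = np.fft.irfft(coeffs, n=steps)
    measured = np.sqrt(np.mean(signal**2))
    return signal * (spec.rms / measured)


def sampled_signal_node(name: str, samples: np.ndarray, dt: float) -> NodeSpec:
    """Node replaying a pre-sampled scalar signal, one value per timestep."""
    samples = np.asarray(samples, dtype=float)
    last = samples.size - 1

    def replay(t):
        idx = min(max(int(round(t / dt)) - 1, 0), last)
        return np.array([samples[idx]])

    return NodeSpec(name, replay, size_out=1)


def communication_channel_model(
    n_neurons_per_ens: int = 50,
    noise: Optional[NoiseSpec] = None,
    probe_tau: float = 0.005,
) -> ExampleModel:
    """Identity routing: noise -> ensemble A -> ensemble B, f(x) = x.

    Both decoded stages are probed; tracking error is measured against the
    stimulus passed through the same filter cascade as the neural path.
    """
    noise = noise or NoiseSpec()
    samples = bandlimited_noise(noise)
    model = ModelSpec("communication_channel")
    stim = sampled_signal_node("stimulus", samples, noise.dt)
    model.add(stim)
    A = EnsembleSpec("A", LIFParams(n_neurons_per_ens), 1)
    B = EnsembleSpec("B", LIFParams(n_neurons_per_ens), 1)
    model.add(A)
    model.add(B)
    model.add(connect(stim, A, name="stim_to_A"))
    model.add(connect(A, B, name="A_to_B"))          # identity decode, 5 ms filter
    p_in = probe(stim, "node_output", name="stim")
    p_a = probe(A, "decoded_output", filter_tau=probe_tau, name="decoded_A")
    p_b = probe(B, "decoded_output", filter_tau=probe_tau, name="decoded_B")
    for p in (p_in, p_a, p_b):
        model.add(p)
    return ExampleModel(
        model=model,
        probes={"stim": p_in, "decoded_A": p_a, "decoded_B": p_b},
        meta={
            "n_neurons_per_ens": n_neurons_per_ens,
            "noise": {"limit_hz": noise.limit, "rms": noise.rms,
                      "seed": noise.seed, "dt": noise.dt,
                      "duration": noise.duration},
            "probe_tau": probe_tau,
        },
        default_duration=noise.duration,
    )


def lorenz_field(params: LorenzParams):
    """Shifted Lorenz vector field (z centred on the attractor)."""
    sigma, rho, beta = params.sigma, params.rho, params.beta

    def f(x):
        return np.array([
            sigma * (x[1] - x[0]),
            -x[0] * x[2] - x[1],
            x[0] * x[1] - beta * (x[2] + rho),
        ])

    return f


def lorenz_model(params: Optional[LorenzParams] = None,
                 probe_tau: float = 0.01) -> ExampleModel:
    """Chaotic attractor in one recurrently connected 3-D ensemble.

    No external input: the bias-current baseline firing kicks the state off
    the origin, after which the recurrent decoded function
    ``g(x) = tau*f(x) + x`` sustains the attractor dynamics.
    """
    params = params or LorenzParams()
    model = ModelSpec("lorenz")
    state = EnsembleSpec("state", LIFParams(params.n_neurons), 3,
                         radius=params.radius)
    model.add(state)
    g = nonlinear_feedback(lorenz_field(params), params.tau)
    model.add(connect(state, state, function=g, filter_tau=params.tau,
                      name="recurrent"))
    p = probe(state, "decoded_output", filter_tau=probe_tau, name="decoded_state")
    model.add(p)
    return ExampleModel(
        model=model,
        probes={"decoded_state": p},
        meta={"sigma": params.sigma, "rho": params.rho, "beta": params.beta,
              "tau": params.tau, "n_neurons": params.n_neurons,
              "radius": params.radius, "probe_tau": probe_tau},
        default_duration=6.0,
    )


def random_unit_vector(n: int, rng) -> np.ndarray:
    rng = np.random.default_rng(rng)
    v = rng.standard_normal(n)
    return v / np.linalg.norm(v)


def circconv_model(
    n: int = 4,
    neurons_per_product: int = 70,
    result_neurons: int = 200,
    seed: int = 0,
    probe_tau: float = 0.005,
) -> ExampleModel:
    """Vector binding: two constant operand nodes drive the convolution
    network, whose output is represented by a Result ensemble.

    The exact circular convolution of the seeded unit-norm operands is the
    target the decoded Result should settle on.
    """
    rng = np.random.default_rng(seed)
    a = random_unit_vector(n, rng)
    b = random_unit_vector(n, rng)
    target = circular_convolution_oracle(a, b)

    model = ModelSpec("circular_convolution")
    in_a = NodeSpec("input_a", a)
    in_b = NodeSpec("input_b", b)
    model.add(in_a)
    model.add(in_b)
    net = circular_convolution_network(n, neurons_per_product)
    model.add(net)
    result = EnsembleSpec("result", LIFParams(result_neurons), n)
    model.add(result)
    model.add(connect(in_a, net.inputs["A"], name="drive_a"))
    model.add(connect(in_b, net.inputs["B"], name="drive_b"))
    model.add(connect(net.outputs["output"], result, name="to_result"))
    p = probe(result, "decoded_output", filter_tau=probe_tau,
              name="decoded_result")
    model.add(p)
    return ExampleModel(
        model=model,
        probes={"decoded_result": p},
        meta={"n": n, "neurons_per_product": neurons_per_product,
              "result_neurons": result_neurons, "operand_seed": seed,
              "operand_a": a.tolist(), "operand_b": b.tolist(),
              "oracle_target": target.tolist(), "probe_tau": probe_tau},
        default_duration=0.2,
    )


def oscillator_model(
    frequency_hz: float = 1.0,
    n_neurons: int = 300,
    tau: float = 0.1,
    kick: float = 5.0,
    kick_duration: float = 0.1,
    probe_tau: float = 0.01,
) -> ExampleModel:
    """Harmonic oscillator at a designed frequency, started by a brief kick."""
    omega = 2.0 * np.pi * frequency_hz
    model = ModelSpec("oscillator")
    net = oscillator(n_neurons, omega, tau)
    model.add(net)

    def kick_fn(t):
        return np.array([kick if t < kick_duration else 0.0])

    kick_node = NodeSpec("kick", kick_fn, size_out=1)
    model.add(kick_node)
    model.add(connect(kick_node, net.inputs["input"], name="kick_in"))
    p = probe(net.outputs["state"], "decoded_output", filter_tau=probe_tau,
              name="decoded_state")
    model.add(p)
    return ExampleModel(
        model=model,
        probes={"decoded_state": p},
        meta={"frequency_hz": frequency_hz, "omega": omega, "tau": tau,
              "n_neurons": n_neurons, "kick": kick,
              "kick_duration": kick_duration, "probe_tau": probe_tau},
        default_duration=6.0,
    )


def integrator_model(
    n_neurons: int = 100,
    tau: float = 0.1,
    input_value: float = 0.5,
    input_duration: float = 1.0,
    probe_tau: float = 0.01,
) -> ExampleModel:
    """Integrator charged by a constant input, then holding its state."""
    model = ModelSpec("integrator_example")
    net = integrator(n_neurons, tau)
    model.add(net)

    def drive(t):
        return np.array([input_value if t <= input_duration else 0.0])

    drive_node = NodeSpec("drive", drive, size_out=1)
    model.add(drive_node)
    model.add(connect(drive_node, net.inputs["input"], name="drive_in"))
    p = probe(net.outputs["state"], "decoded_output", filter_tau=probe_tau,
              name="decoded_state")
    model.add(p)
    return ExampleModel(
        model=model,
        probes={"decoded_state": p},
        meta={"n_neurons": n_neurons, "tau": tau, "input_value": input_value,
              "input_duration": input_duration, "probe_tau": probe_tau},
        default_duration=1.5,
    )
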