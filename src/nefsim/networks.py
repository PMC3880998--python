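"""Reusable network constructors and the dynamics-principle translation.

A first-order synaptic filter with time constant ``tau`` turns a desired
dynamical system ``dx/dt = A x + B u`` into neural circuitry via the
recurrent transform ``tau*A + I`` and input transform ``tau*B``; nonlinear
vector fields ``f`` generalize to the recurrent decoded function
``g(x) = tau*f(x) + x``.  Circular convolution (vector binding) is built by
pairing discrete-Fourier-transform components of the two operands in small
two-dimensional product ensembles and reassembling the products through the
inverse transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model import ConnectionSpec, EnsembleSpec, NetworkSpec, NodeSpec, connect
from .neurons import LIFParams

__all__ = [
    "LinearSystemSpec",
    "DFTPlan",
    "dynamics_transforms",
    "nonlinear_feedback",
    "integrator",
    "oscillator",
    "dft_plan",
    "apply_dft_plan",
    "circular_convolution_oracle",
    "circular_convolution_network",
]


@dataclass
class LinearSystemSpec:
    """A linear system ``dx/dt = A x + B u`` (A: [d x d], B: [d x u], 1/s)."""

    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if self.A.shape[0] != self.A.shape[1]:
            raise ValueError(f"A must be square, got {self.A.shape}")
        if self.B.shape[0] != self.A.shape[0]:
            raise ValueError(
                f"B has {self.B.shape[0]} rows but A is {self.A.shape[0]}-dim"
            )


def dynamics_transforms(sys: LinearSystemSpec, tau: float):
    """Map ``dx/dt = A x + B u`` onto a first-order synapse of constant tau.

    Returns ``(recurrent, input)`` transforms ``tau*A + I`` and ``tau*B``:
    with the recurrent connection filtered by tau, the represented state
    obeys the requested dynamics.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    d = sys.A.shape[0]
    return tau * sys.A + np.eye(d), tau * sys.B


def nonlinear_feedback(f: Callable, tau: float) -> Callable:
    """Recurrent decoded function ``g(x) = tau*f(x) + x`` realizing dx/dt = f(x)."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")

    def g(x):
        return tau * np.asarray(f(x), dtype=float) + np.asarray(x, dtype=float)

    return g


def integrator(n_neurons: int, tau: float = 0.1, label: str = "integrator",
               dimensions: int = 1, radius: float = 1.0) -> NetworkSpec:
    """A memory network: one recurrently connected ensemble integrating input.

    The recurrent connection carries the identity with filter tau; the
    exposed input node feeds the ensemble through ``tau * I`` so the state
    obeys ``dx/dt = u``.
    """
    net = NetworkSpec(label)
    inp = net.add(NodeSpec(f"{label}.input", None, size_in=dimensions))
    ens = net.add(EnsembleSpec(f"{label}.state", LIFParams(n_neurons),
                               dimensions, radius=radius))
    net.add(connect(ens, ens, transform=np.eye(dimensions), filter_tau=tau,
                    name=f"{label}.recurrent"))
    net.add(connect(inp, ens, transform=tau * np.eye(dimensions), filter_tau=tau,
                    name=f"{label}.drive"))
    net.inputs["input"] = inp
    net.outputs["state"] = ens
    return net


def oscillator(n_neurons: int, omega: float, tau: float = 0.1,
               label: str = "oscillator", radius: float = 1.0) -> NetworkSpec:
    """A neural harmonic oscillator rotating at ``omega`` rad/s.

    Implements ``A = [[0, w], [-w, 0]]`` with a scalar kick input entering
    the first state dimension; drive the exposed input briefly to set the
    oscillation amplitude.
    """
    sys = LinearSystemSpec([[0.0, omega], [-omega, 0.0]], [[1.0], [0.0]])
    recurrent, inp_tf = dynamics_transforms(sys, tau)
    net = NetworkSpec(label)
    inp = net.add(NodeSpec(f"{label}.input", None, size_in=1))
    ens = net.add(EnsembleSpec(f"{label}.state", LIFParams(n_neurons), 2,
                               radius=radius))
    net.add(connect(ens, ens, transform=recurrent, filter_tau=tau,
                    name=f"{label}.recurrent"))
    net.add(connect(inp, ens, transform=inp_tf, filter_tau=tau,
                    name=f"{label}.drive"))
    net.inputs["input"] = inp
    net.outputs["state"] = ens
    return net


# ---------------------------------------------------------------------------
# circular convolution


@dataclass
class DFTPlan:
    """Real-arithmetic factorization of circular convolution.

    Each scalar product pairs one spectrum component of operand A with one
    of operand B: ``result = inverse @ ((forward_a @ a) * (forward_b @ b))``
    holds exactly.  Real spectrum components (frequency 0, and n/2 for even
    n) need one product each; complex components need four (the real/real,
    imag/imag, real/imag and imag/real parts of ``(A + ai)(C + ci)``), for
    ``2n - 2`` products when n is even and ``2n - 1`` when odd.
    """

    n: int
    forward_a: np.ndarray       # [P x n]
    forward_b: np.ndarray       # [P x n]
    inverse: np.ndarray         # [n x P]
    component_pairs: list = field(default_factory=list)

    @property
    def n_products(self) -> int:
        return self.forward_a.shape[0]


def dft_plan(n: int) -> DFTPlan:
    """Build the product pairing for n-dimensional circular convolution."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    j = np.arange(n)
    rows_a, rows_b, cols, pairs = [], [], [], []

    def add_product(u, v, out_col, tag):
        rows_a.append(u)
        rows_b.append(v)
        cols.append(out_col)
        pairs.append(tag)

    for k in range(n // 2 + 1):
        theta = 2.0 * np.pi * k * j / n
        re = np.cos(theta)           # real part row of the k-th DFT component
        im = -np.sin(theta)          # imaginary part row
        out_cos = np.cos(theta) / n
        out_sin = np.sin(theta) / n
        if k == 0 or (n % 2 == 0 and k == n // 2):
            add_product(re, re, out_cos, (k, "re*re"))
        else:
            # (A + ai)(C + ci): conjugate-symmetric components count twice
            add_product(re, re, 2.0 * out_cos, (k, "re*re"))
            add_product(im, im, -2.0 * out_cos, (k, "im*im"))
            add_product(re, im, -2.0 * out_sin, (k, "re*im"))
            add_product(im, re, -2.0 * out_sin, (k, "im*re"))
    return DFTPlan(
        n=n,
        forward_a=np.array(rows_a),
        forward_b=np.array(rows_b),
        inverse=np.array(cols).T,
        component_pairs=pairs,
    )


def apply_dft_plan(plan: DFTPlan, a, b) -> np.ndarray:
    """Evaluate the plan with exact scalar products (no neurons)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return plan.inverse @ ((plan.forward_a @ a) * (plan.forward_b @ b))


def circular_convolution_oracle(a, b) -> np.ndarray:
    """Reference circular convolution by direct summation.

    ``c[j] = sum_i a[i] * b[(j - i) mod n]``; O(n^2), used as the
    independent check for the DFT factorization and the neural network.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"operand shapes differ: {a.shape} vs {b.shape}")
    n = a.size
    c = np.zeros(n)
    for jj in range(n):
        for i in range(n):
            c[jj] += a[i] * b[(jj - i) % n]
    return c


def _product_of_dims(x):
    return x[0] * x[1]


def circular_convolution_network(
    n: int,
    neurons_per_product: int = 70,
    label: str = "circconv",
    input_scale: float = 1.0 / np.sqrt(2.0),
) -> NetworkSpec:
    """Neural circular convolution of two n-dimensional vectors.

    One two-dimensional ensemble per DFT product represents a (scaled)
    spectrum-component pair and decodes the product of its two dimensions;
    forward transforms route the operands in, the inverse transform
    reassembles the n-dimensional result at the exposed ``output`` node.
    Operand components are scaled by ``input_scale`` (default 1/sqrt(2)) so
    unit-norm operands keep product-ensemble inputs near the unit ball; the
    inverse transform un-scales.
    """
    if n < 1 or neurons_per_product < 1:
        raise ValueError("n and neurons_per_product must be >= 1")
    plan = dft_plan(n)
    net = NetworkSpec(label)
    in_a = net.add(NodeSpec(f"{label}.A", None, size_in=n))
    in_b = net.add(NodeSpec(f"{label}.B", None, size_in=n))
    out = net.add(NodeSpec(f"{label}.output", None, size_in=n))
    s = input_scale
    for p in range(plan.n_products):
        # scaled spectrum components each lie in [-1, 1] for unit-norm
        # operands, so the 2-D pair lives in the unit square: radius sqrt(2)
        ens = net.add(EnsembleSpec(f"{label}.product{p}",
                                   LIFParams(neurons_per_product), 2,
                                   radius=np.sqrt(2.0)))
        ta = np.vstack([s * plan.forward_a[p], np.zeros(n)])
        tb = np.vstack([np.zeros(n), s * plan.forward_b[p]])
        net.add(connect(in_a, ens, transform=ta, name=f"{label}.in_a{p}"))
        net.add(connect(in_b, ens, transform=tb, name=f"{label}.in_b{p}"))
        net.add(connect(ens, out, function=_product_of_dims,
                        transform=(plan.inverse[:, p] / s**2)[:, None],
                        name=f"{label}.out{p}"))
    net.inputs["A"] = in_a
    net.inputs["B"] = in_b
    net.outputs["output"] = out
    return net
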