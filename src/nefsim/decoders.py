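"""Least-squares decoder solving and factored connection weights.

Decoders are the linear read-out weights ``D`` [n_neurons x k] such that
``A @ D`` approximates the target function values ``Y`` at a set of sampled
evaluation points, where ``A`` holds the analytic tuning-curve activities at
those points.  A full synaptic weight matrix between two populations is the
low-rank product ``diag(gain) @ encoders @ transform @ D.T``; simulations
normally keep the factors separate and multiply through them in sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "DecoderSolveProblem",
    "sample_eval_points",
    "solve_decoders",
    "decode",
    "full_weight_matrix",
]

#: Default ridge regularization, as a fraction of the maximum activity.
DEFAULT_REGULARIZATION = 0.1


@dataclass
class DecoderSolveProblem:
    """A regularized least-squares decoder problem.

    ``activities`` is [m points x n neurons] in Hz; ``targets`` is [m x k]
    desired decoded values; ``regularization`` is the ridge parameter sigma
    expressed as a fraction of the maximum activity entry.
    """

    activities: np.ndarray
    targets: np.ndarray
    regularization: float = DEFAULT_REGULARIZATION

    def __post_init__(self) -> None:
        self.activities = np.atleast_2d(np.asarray(self.activities, dtype=float))
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
        if self.activities.shape[0] != self.targets.shape[0]:
            raise ValueError(
                f"activities has {self.activities.shape[0]} rows but targets "
                f"has {self.targets.shape[0]}"
            )
        if self.regularization < 0:
            raise ValueError("regularization must be non-negative")


def sample_eval_points(m: int, d: int, rng) -> np.ndarray:
    """Sample ``m`` points uniformly from the closed unit ``d``-ball.

    Direction uniform on the sphere, radius drawn as U^(1/d) so volume is
    covered uniformly.  Deterministic given a seed or Generator.
    """
    if m < 1 or d < 1:
        raise ValueError("m and d must be >= 1")
    rng = np.random.default_rng(rng)
    directions = rng.standard_normal((m, d))
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    radii = rng.uniform(size=(m, 1)) ** (1.0 / d)
    return directions / norms * radii


def default_n_eval_points(d: int) -> int:
    """Default evaluation-point count: max(500, 100 * d)."""
    return max(500, 100 * d)


def solve_decoders(problem: DecoderSolveProblem) -> np.ndarray:
    """Solve the regularized least-squares problem for decoders ``D`` [n x k].

    Minimizes ``||A D - Y||^2 + m * (sigma * a_max)^2 * ||D||^2`` via the
    normal equations with a direct symmetric solve:

        D = (A.T A + m (sigma a_max)^2 I)^{-1} A.T Y

    where ``a_max`` is the largest activity.  Fully deterministic.  Raises
    ``ValueError`` naming silent neurons when the problem is degenerate
    (a neuron with all-zero activity and no regularization to damp it).
    """
    A, Y = problem.activities, problem.targets
    m, n = A.shape
    a_max = A.max(initial=0.0)
    if a_max == 0.0:
        raise ValueError("all neurons are silent over the evaluation points")
    silent = np.where(~A.any(axis=0))[0]
    if silent.size and problem.regularization == 0:
        raise ValueError(
            f"silent neurons {silent.tolist()} make the unregularized "
            "least-squares problem singular"
        )
    G = A.T @ A
    lam = m * (problem.regularization * a_max) ** 2
    G[np.diag_indices(n)] += lam
    return scipy.linalg.solve(G, A.T @ Y, assume_a="pos")


def decode(activities: np.ndarray, decoders: np.ndarray) -> np.ndarray:
    """Linear read-out: matrix product of activities [t x n] and decoders [n x k]."""
    return np.asarray(activities, dtype=float) @ np.asarray(decoders, dtype=float)


def full_weight_matrix(
    decoders: np.ndarray,
    transform: np.ndarray,
    encoders: np.ndarray,
    gains: np.ndarray,
) -> np.ndarray:
    """Assemble the explicit connection weight matrix ``W`` [n_post x n_pre].

    ``W = diag(gains) @ encoders @ transform @ decoders.T``; entry (i, j) is
    the weight from presynaptic neuron j onto postsynaptic neuron i.  The
    rank of W is bounded by min(k, d_post) — the factored form this product
    expands.
    """
    decoders = np.atleast_2d(np.asarray(decoders, dtype=float))
    transform = np.atleast_2d(np.asarray(transform, dtype=float))
    encoders = np.atleast_2d(np.asarray(encoders, dtype=float))
    gains = np.asarray(gains, dtype=float)
    return gains[:, None] * (encoders @ transform @ decoders.T)
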