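"""Dynamics translation, integrator, DFT product pairing, circular convolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nefsim import EnsembleSpec, LIFParams, ModelSpec, NodeSpec, build, connect, probe
from nefsim.networks import (
    LinearSystemSpec,
    apply_dft_plan,
    circular_convolution_network,
    circular_convolution_oracle,
    dft_plan,
    dynamics_transforms,
    integrator,
    nonlinear_feedback,
)


class TestDynamicsTransforms:
    def test_integrator_mapping(self):
        rec, inp = dynamics_transforms(LinearSystemSpec([[0.0]], [[1.0]]), tau=0.1)
        assert np.allclose(rec, [[1.0]])
        assert np.allclose(inp, [[0.1]])

    def test_harmonic_oscillator_mapping(self):
        omega = 2 * np.pi * 1.0
        rec, _ = dynamics_transforms(
            LinearSystemSpec([[0.0, omega], [-omega, 0.0]], [[1.0], [0.0]]), tau=0.1
        )
        assert np.allclose(rec, [[1.0, 0.2 * np.pi], [-0.2 * np.pi, 1.0]])

    def test_self_decay_cancels_recurrence(self):
        tau = 0.05
        rec, _ = dynamics_transforms(
            LinearSystemSpec(-np.eye(2) / tau, np.zeros((2, 1))), tau=tau
        )
        assert np.allclose(rec, 0.0)

    def test_nonlinear_feedback_zero_field_is_identity(self):
        g = nonlinear_feedback(lambda x: np.zeros_like(x), tau=0.1)
        x = np.array([0.3, -0.7])
        assert np.allclose(g(x), x)

    def test_nonlinear_feedback_reduces_to_linear_mapping(self):
        A = np.array([[0.0, 1.0], [-1.0, 0.0]])
        tau = 0.08
        g = nonlinear_feedback(lambda x: A @ x, tau=tau)
        rec, _ = dynamics_transforms(LinearSystemSpec(A, np.zeros((2, 1))), tau=tau)
        x = np.array([0.4, 0.2])
        assert np.allclose(g(x), rec @ x)


class TestIntegratorNetwork:
    def test_structure_one_ensemble_two_connections(self):
        from nefsim.model import ConnectionSpec

        m = ModelSpec("m")
        m.add(integrator(50, 0.1))
        flat = m.flattened()
        assert sum(isinstance(o, EnsembleSpec) for o in flat) == 1
        assert sum(isinstance(o, ConnectionSpec) for o in flat) == 2

    def test_integrates_constant_input(self):
        m = ModelSpec("m")
        net = integrator(100, 0.1)
        m.add(net)
        drive = NodeSpec("u", [0.5])
        m.add(drive)
        m.add(connect(drive, net.inputs["input"]))
        p = probe(net.outputs["state"], "decoded_output", filter_tau=0.01, name="p")
        m.add(p)
        rec = build(m, seed=0).run(1.0)[p]
        assert rec.values[-1, 0] == pytest.approx(0.5, abs=0.1)

    def test_holds_zero_without_input(self):
        m = ModelSpec("m")
        net = integrator(100, 0.1)
        m.add(net)
        p = probe(net.outputs["state"], "decoded_output", filter_tau=0.01, name="p")
        m.add(p)
        rec = build(m, seed=0).run(1.0)[p]
        assert np.all(np.abs(rec.values) < 0.1)


class TestDFTPlan:
    def test_product_counts(self):
        assert dft_plan(4).n_products == 6
        assert dft_plan(2).n_products == 2
        for n in range(1, 17):
            expected = 2 * n - 2 if (n % 2 == 0 and n > 1) else 2 * n - 1
            assert dft_plan(n).n_products == expected

    def test_two_dimensional_convolution_closed_form(self):
        plan = dft_plan(2)
        a, b = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        assert np.allclose(apply_dft_plan(plan, a, b), [11.0, 10.0])

    def test_exactness_against_direct_summation(self, rng):
        for n in range(1, 17):
            plan = dft_plan(n)
            for _ in range(7):
                a, b = rng.standard_normal(n), rng.standard_normal(n)
                assert np.allclose(
                    apply_dft_plan(plan, a, b),
                    circular_convolution_oracle(a, b),
                    atol=1e-10,
                )


class TestConvolutionOracle:
    def test_unit_impulse_is_identity_element(self, rng):
        b = rng.standard_normal(4)
        assert np.allclose(circular_convolution_oracle([1, 0, 0, 0], b), b)

    def test_direct_summation_example(self):
        assert np.allclose(circular_convolution_oracle([1.0, 2.0], [3.0, 4.0]),
                           [11.0, 10.0])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000),
           n=st.integers(min_value=1, max_value=8))
    def test_commutativity(self, seed, n):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        assert np.allclose(circular_convolution_oracle(a, b),
                           circular_convolution_oracle(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            circular_convolution_oracle([1.0, 2.0], [1.0, 2.0, 3.0])


class TestConvolutionNetwork:
    def test_four_dimensional_network_has_six_2d_product_ensembles(self):
        net = circular_convolution_network(4, 70)
        ensembles = [o for o in net.members if isinstance(o, EnsembleSpec)]
        assert len(ensembles) == 6
        assert all(e.dimensions == 2 for e in ensembles)

    def test_product_ensemble_decodes_xy_accurately(self):
        """A 70-neuron 2-D ensemble decodes x0*x1 with RMSE < 0.1 on the square."""
        from nefsim.builder import resolve_ensemble
        from nefsim.decoders import DecoderSolveProblem, decode, solve_decoders
        from nefsim.decoders import sample_eval_points
        from nefsim.neurons import tuning_curves

        ens = EnsembleSpec("p", LIFParams(70), 2, radius=np.sqrt(2.0))
        resolved = resolve_ensemble(ens, np.random.default_rng(3))
        train = sample_eval_points(500, 2, 4) * ens.radius
        A = tuning_curves(resolved, train)
        D = solve_decoders(
            DecoderSolveProblem(A, (train[:, 0] * train[:, 1])[:, None]))
        gx, gy = np.meshgrid(np.linspace(-1, 1, 21), np.linspace(-1, 1, 21))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        est = decode(tuning_curves(resolved, grid), D)[:, 0]
        err = np.sqrt(np.mean((est - grid[:, 0] * grid[:, 1]) ** 2))
        assert err < 0.1

    def test_identity_operand_passes_other_operand_through(self):
        from nefsim.metrics import cosine_similarity_trace

        m = ModelSpec("m")
        e0 = np.array([1.0, 0.0, 0.0, 0.0])
        b = np.array([0.4, -0.3, 0.6, 0.2])
        net = circular_convolution_network(4, 70)
        m.add(net)
        na, nb = NodeSpec("a", e0), NodeSpec("b", b)
        m.add(na)
        m.add(nb)
        m.add(connect(na, net.inputs["A"]))
        m.add(connect(nb, net.inputs["B"]))
        p = probe(net.outputs["output"], "node_output", filter_tau=0.005, name="p")
        m.add(p)
        rec = build(m, seed=0).run(0.2)[p]
        sims = cosine_similarity_trace(rec.values[100:], b)
        assert np.all(sims > 0.8)
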