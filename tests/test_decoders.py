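"""Decoder solving, evaluation points, factored weights."""

import numpy as np
import pytest

from nefsim.decoders import (
    DecoderSolveProblem,
    decode,
    full_weight_matrix,
    sample_eval_points,
    solve_decoders,
)


def ridge_oracle(A, Y, sigma):
    """Independent route: augmented least squares via numpy's SVD solver."""
    m, n = A.shape
    lam = m * (sigma * A.max()) ** 2
    aug_A = np.vstack([A, np.sqrt(lam) * np.eye(n)])
    aug_Y = np.vstack([Y, np.zeros((n, Y.shape[1]))])
    return np.linalg.lstsq(aug_A, aug_Y, rcond=None)[0]


class TestEvalPoints:
    def test_points_lie_in_unit_ball(self):
        pts = sample_eval_points(2000, 5, 0)
        assert np.all(np.linalg.norm(pts, axis=1) <= 1.0 + 1e-12)

    def test_one_dimensional_moments(self):
        pts = sample_eval_points(2000, 1, 3)
        assert abs(pts.mean()) < 0.05
        assert pts.min() < -0.9 and pts.max() > 0.9

    def test_deterministic_given_seed(self):
        assert np.array_equal(sample_eval_points(100, 3, 7),
                              sample_eval_points(100, 3, 7))


class TestSolveDecoders:
    def test_identity_activities_unregularized(self):
        D = solve_decoders(DecoderSolveProblem(np.eye(2), [[2.0], [3.0]], 0.0))
        assert np.allclose(D, [[2.0], [3.0]])

    def test_matches_pseudoinverse_when_unregularized(self, rng):
        A = rng.uniform(0, 100, size=(80, 20))
        Y = rng.standard_normal((80, 3))
        D = solve_decoders(DecoderSolveProblem(A, Y, 0.0))
        D_pinv = np.linalg.lstsq(A, Y, rcond=None)[0]
        assert np.allclose(D, D_pinv, atol=1e-8)

    def test_matches_ridge_oracle_across_regularizations(self, rng):
        for sigma in (0.01, 0.1, 1.0):
            A = rng.uniform(0, 200, size=(150, 60))
            Y = rng.standard_normal((150, 2))
            D = solve_decoders(DecoderSolveProblem(A, Y, sigma))
            assert np.allclose(D, ridge_oracle(A, Y, sigma), atol=1e-8)

    def test_heavy_regularization_shrinks_to_zero(self, rng):
        A = rng.uniform(0, 100, size=(50, 10))
        Y = rng.standard_normal((50, 1))
        D = solve_decoders(DecoderSolveProblem(A, Y, 1e6))
        assert np.all(np.abs(D) < 1e-6)

    def test_all_silent_neurons_rejected(self):
        with pytest.raises(ValueError, match="silent"):
            solve_decoders(DecoderSolveProblem(np.zeros((10, 5)), np.zeros((10, 1))))

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            DecoderSolveProblem(np.ones((4, 2)), np.ones((3, 1)))


class TestDecode:
    def test_zero_activity_decodes_zero(self):
        assert np.all(decode(np.zeros((5, 3)), np.ones((3, 2))) == 0)

    def test_one_hot_selects_decoder_row(self, rng):
        D = rng.standard_normal((4, 2))
        a = np.zeros((1, 4))
        a[0, 2] = 1.0
        assert np.allclose(decode(a, D), D[2])

    def test_identity_function_decode_accuracy(self):
        """A resolved 100-neuron 1-D ensemble reconstructs x with RMSE < 0.05."""
        from nefsim.builder import resolve_ensemble
        from nefsim.model import EnsembleSpec
        from nefsim.neurons import LIFParams, tuning_curves

        ens = EnsembleSpec("e", LIFParams(100), 1)
        resolved = resolve_ensemble(ens, np.random.default_rng(5))
        train = sample_eval_points(500, 1, 6)
        A = tuning_curves(resolved, train)
        D = solve_decoders(DecoderSolveProblem(A, train))
        grid = np.linspace(-0.8, 0.8, 81)[:, None]
        xhat = decode(tuning_curves(resolved, grid), D)
        assert np.sqrt(np.mean((xhat - grid) ** 2)) < 0.05

    def test_error_decreases_with_population_size(self):
        from nefsim.builder import resolve_ensemble
        from nefsim.model import EnsembleSpec
        from nefsim.neurons import LIFParams, tuning_curves

        grid = np.linspace(-0.8, 0.8, 81)[:, None]
        errors = []
        for n in (10, 50, 100, 500):
            ens = EnsembleSpec("e", LIFParams(n), 1)
            resolved = resolve_ensemble(ens, np.random.default_rng(0))
            train = sample_eval_points(500, 1, 1)
            A = tuning_curves(resolved, train)
            D = solve_decoders(DecoderSolveProblem(A, train))
            xhat = decode(tuning_curves(resolved, grid), D)
            errors.append(np.sqrt(np.mean((xhat - grid) ** 2)))
        assert errors == sorted(errors, reverse=True)


class TestFullWeightMatrix:
    def test_scalar_case_is_rank_one_outer_product(self, rng):
        W = full_weight_matrix(rng.standard_normal((30, 1)), np.eye(1),
                               rng.standard_normal((20, 1)),
                               rng.uniform(1, 5, 20))
        assert np.linalg.matrix_rank(W) == 1

    def test_rank_bounded_by_dimensionality(self, rng):
        W = full_weight_matrix(rng.standard_normal((40, 2)), np.eye(2),
                               rng.standard_normal((50, 2)),
                               rng.uniform(1, 5, 50))
        assert W.shape == (50, 40)
        assert np.linalg.matrix_rank(W) <= 2

    def test_expanded_product_equals_factored_application(self, rng):
        """W @ activity == gains * (E @ (T @ (D.T @ activity))) by associativity."""
        D = rng.standard_normal((40, 3))
        T = rng.standard_normal((2, 3))
        E = rng.standard_normal((25, 2))
        g = rng.uniform(1, 10, 25)
        act = rng.uniform(0, 400, 40)
        W = full_weight_matrix(D, T, E, g)
        factored = g * (E @ (T @ (D.T @ act)))
        assert np.allclose(W @ act, factored, atol=1e-10)
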