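"""Tests of the network building blocks and the composite loss.

Every analytic gradient in the training path is checked against central
finite differences; the variance terms are checked against loop-style
oracle values computed independently of the vectorized implementation.
"""

import numpy as np
import pytest

from protopolicy.nn import (
    Adam,
    DPNNetwork,
    MLP,
    bce_grad,
    bce_loss,
    combined_loss,
    inter_variance,
    intra_variance,
    prototype_distances,
    prototype_distances_backward,
    prototype_variance_grad,
    prototype_variance_loss,
    reconstruction_grad,
    reconstruction_loss,
)

# worked examples: a 3x3 prototype-outcome matrix with strong across-treatment
# spread inside each subgroup, and one whose rows are nearly constant
HIGH_INTRA = np.array([[0.3, 0.25, 0.7], [0.35, 0.2, 0.65], [0.8, 0.02, 0.03]])
LOW_INTRA = np.array([[0.81, 0.8, 0.83], [0.45, 0.44, 0.47], [0.19, 0.2, 0.18]])


def loop_intra(Y):
    return sum(((row - row.mean()) ** 2).sum() for row in Y) / Y.shape[0]


def loop_inter(Y):
    return sum(((col - col.mean()) ** 2).sum() for col in Y.T) / Y.shape[0]


class TestMLP:
    def test_zero_weights_give_zero_output(self, rng):
        mlp = MLP([4, 3, 2], "linear", rng)
        for W in mlp.W:
            W[...] = 0.0
        for b in mlp.b:
            b[...] = 0.0
        out, _ = mlp.forward(rng.standard_normal((5, 4)))
        assert np.all(out == 0.0)

    def test_identity_weights_pass_inputs_through(self, rng):
        mlp = MLP([3, 3], "linear", rng)
        mlp.W[0][...] = np.eye(3)
        mlp.b[0][...] = 0.0
        X = rng.standard_normal((4, 3))
        out, _ = mlp.forward(X)
        assert np.allclose(out, X)

    @pytest.mark.parametrize("out_act", ["linear", "sigmoid"])
    def test_gradients_match_finite_differences(self, rng, out_act):
        mlp = MLP([4, 6, 2], out_act, rng)
        X = rng.standard_normal((5, 4))
        G = rng.standard_normal((5, 2))  # arbitrary linear functional of output

        def scalar_loss():
            out, _ = mlp.forward(X)
            return float((G * out).sum())

        out, cache = mlp.forward(X)
        dX, grads = mlp.backward(cache, G)
        h = 1e-6
        for p, g in zip(mlp.params, grads):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = p[i]
                p[i] = orig + h
                up = scalar_loss()
                p[i] = orig - h
                down = scalar_loss()
                p[i] = orig
                assert (up - down) / (2 * h) == pytest.approx(g[i], rel=1e-4, abs=1e-7)


class TestPrototypeDistances:
    def test_three_four_five_triangle(self):
        D = prototype_distances(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]))
        assert D[0, 0] == pytest.approx(25.0)
        D = prototype_distances(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]), squared=False)
        assert D[0, 0] == pytest.approx(5.0)

    def test_zero_distance_to_itself(self, rng):
        z = rng.standard_normal((1, 6))
        assert prototype_distances(z, z)[0, 0] == pytest.approx(0.0)

    def test_matches_pairwise_loop(self, rng):
        Z = rng.standard_normal((3, 5))
        P = rng.standard_normal((4, 5))
        D = prototype_distances(Z, P)
        for i in range(3):
            for j in range(4):
                assert D[i, j] == pytest.approx(((Z[i] - P[j]) ** 2).sum())

    def test_backward_matches_finite_differences(self, rng):
        Z = rng.standard_normal((3, 4))
        P = rng.standard_normal((5, 4))
        G = rng.standard_normal((3, 5))
        dZ, dP = prototype_distances_backward(Z, P, G)
        h = 1e-6
        for arr, grad in ((Z, dZ), (P, dP)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + h
                up = float((G * prototype_distances(Z, P)).sum())
                arr[i] = orig - h
                down = float((G * prototype_distances(Z, P)).sum())
                arr[i] = orig
                assert (up - down) / (2 * h) == pytest.approx(grad[i], rel=1e-5, abs=1e-8)


class TestAccuracyLoss:
    def test_half_probability_gives_log_two(self):
        assert bce_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(0.6931, abs=1e-4)

    def test_confident_correct_prediction_vanishes(self):
        assert bce_loss(np.array([1.0 - 1e-9]), np.array([1.0])) == pytest.approx(0.0, abs=1e-5)

    def test_batch_matches_hand_sum(self):
        p = np.array([0.9, 0.2, 0.6, 0.4])
        y = np.array([1.0, 0.0, 0.0, 1.0])
        expected = -(np.log(0.9) + np.log(0.8) + np.log(0.4) + np.log(0.4)) / 4
        assert bce_loss(p, y) == pytest.approx(expected)

    def test_grad_matches_finite_differences(self):
        p = np.array([0.9, 0.2, 0.6, 0.4])
        y = np.array([1.0, 0.0, 0.0, 1.0])
        g = bce_grad(p, y)
        h = 1e-7
        for i in range(4):
            pp = p.copy()
            pp[i] += h
            pm = p.copy()
            pm[i] -= h
            fd = (bce_loss(pp, y) - bce_loss(pm, y)) / (2 * h)
            assert fd == pytest.approx(g[i], rel=1e-5)

    def test_clamped_probabilities_stay_finite(self):
        assert np.isfinite(bce_loss(np.array([0.0, 1.0]), np.array([1.0, 0.0])))


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self, rng):
        X = rng.standard_normal((4, 6))
        assert reconstruction_loss(X, X.copy()) == 0.0

    def test_three_four_five_norm(self):
        assert reconstruction_loss(np.array([[3.0, 4.0]]), np.array([[0.0, 0.0]])) == pytest.approx(5.0)

    def test_batch_matches_loop(self, rng):
        X = rng.standard_normal((6, 5))
        Xh = rng.standard_normal((6, 5))
        expected = np.mean([np.sqrt(((X[i] - Xh[i]) ** 2).sum()) for i in range(6)])
        assert reconstruction_loss(X, Xh) == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 3)), np.zeros((2, 4)))

    def test_grad_matches_finite_differences(self, rng):
        X = rng.standard_normal((3, 4))
        Xh = rng.standard_normal((3, 4))
        g = reconstruction_grad(X, Xh)
        h = 1e-6
        it = np.nditer(Xh, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = Xh[i]
            Xh[i] = orig + h
            up = reconstruction_loss(X, Xh)
            Xh[i] = orig - h
            down = reconstruction_loss(X, Xh)
            Xh[i] = orig
            assert (up - down) / (2 * h) == pytest.approx(g[i], rel=1e-5)


class TestVarianceTerms:
    def test_constant_matrix_has_no_variance(self):
        Y = np.full((4, 3), 0.5)
        assert intra_variance(Y) == 0.0
        assert inter_variance(Y) == 0.0
        assert prototype_variance_loss(Y, 0.85) == 0.0

    def test_worked_high_intra_example(self):
        assert intra_variance(HIGH_INTRA) == pytest.approx(0.2090444, abs=1e-6)
        assert intra_variance(HIGH_INTRA) == pytest.approx(loop_intra(HIGH_INTRA))

    def test_worked_low_intra_example(self):
        assert intra_variance(LOW_INTRA) == pytest.approx(0.0003778, abs=1e-6)
        assert inter_variance(LOW_INTRA) == pytest.approx(0.1961111, abs=1e-6)
        assert inter_variance(LOW_INTRA) == pytest.approx(loop_inter(LOW_INTRA))

    def test_identical_rows_have_no_inter_variance(self):
        Y = np.tile(np.array([[0.2, 0.7, 0.4]]), (5, 1))
        assert inter_variance(Y) == pytest.approx(0.0)

    def test_row_and_column_permutation_invariance(self, rng):
        Y = rng.random((4, 3))
        rp = rng.permutation(4)
        cp = rng.permutation(3)
        assert intra_variance(Y[rp][:, cp]) == pytest.approx(intra_variance(Y))
        assert inter_variance(Y[rp][:, cp]) == pytest.approx(inter_variance(Y))

    def test_weighted_combination_and_limit(self):
        L3 = prototype_variance_loss(HIGH_INTRA, 0.85)
        assert L3 == pytest.approx(-(0.85 * 0.2090444 + 0.15 * 0.1531778), abs=1e-6)
        assert L3 <= 0.0
        near_one = prototype_variance_loss(HIGH_INTRA, 1 - 1e-12)
        assert near_one == pytest.approx(-intra_variance(HIGH_INTRA))

    def test_alternative_normalization(self):
        assert intra_variance(HIGH_INTRA, "lk") == pytest.approx(0.2090444 / 3, abs=1e-6)

    def test_grad_matches_finite_differences(self, rng):
        Y = rng.random((3, 4))
        g = prototype_variance_grad(Y, 0.85)
        h = 1e-7
        it = np.nditer(Y, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = Y[i]
            Y[i] = orig + h
            up = prototype_variance_loss(Y, 0.85)
            Y[i] = orig - h
            down = prototype_variance_loss(Y, 0.85)
            Y[i] = orig
            assert (up - down) / (2 * h) == pytest.approx(g[i], rel=1e-4, abs=1e-9)


class TestCombinedLoss:
    def test_weights_zero_reduces_to_accuracy(self):
        assert combined_loss(0.7, 10.0, -0.2, 0.0, 0.0) == 0.7

    def test_reference_arithmetic(self):
        assert combined_loss(0.7, 10.0, -0.2, 0.01, 0.05) == pytest.approx(0.79)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            combined_loss(1.0, 1.0, -1.0, -0.1, 0.0)


class TestDPNNetwork:
    def make(self, rng, **kw):
        kw.setdefault("encoder_hidden", (5,))
        kw.setdefault("classifier_hidden", (7,))
        return DPNNetwork(6, 3, 4, 3, rng=rng, **kw)

    def test_encode_decode_shapes(self, rng):
        net = self.make(rng)
        X = rng.standard_normal((8, 6))
        Z = net.encode(X)
        assert Z.shape == (8, 3)
        assert net.reconstruct(Z).shape == (8, 6)

    def test_dimension_mismatch_rejected(self, rng):
        net = self.make(rng)
        with pytest.raises(ValueError):
            net.encode(rng.standard_normal((4, 5)))
        with pytest.raises(ValueError):
            net.reconstruct(rng.standard_normal((4, 2)))

    def test_zeroed_head_predicts_one_half(self, rng):
        net = self.make(rng)
        net.classifier.W[-1][...] = 0.0
        net.classifier.b[-1][...] = 0.0
        D = net.distances(net.encode(rng.standard_normal((5, 6))))
        T = np.eye(3)[rng.integers(0, 3, 5)]
        assert np.allclose(net.classify(D, T), 0.5)
        assert np.allclose(net.prototype_outcome_matrix(), 0.5)

    def test_classify_outputs_are_probabilities_and_deterministic(self, rng):
        net = self.make(rng)
        D = net.distances(net.encode(rng.standard_normal((50, 6))))
        T = np.eye(3)[rng.integers(0, 3, 50)]
        p1 = net.classify(D, T)
        p2 = net.classify(D, T)
        assert np.array_equal(p1, p2)
        assert np.all((p1 >= 0) & (p1 <= 1))

    def test_prototype_outcome_matrix_shape_and_symmetry(self, rng):
        net = self.make(rng)
        Y = net.prototype_outcome_matrix()
        assert Y.shape == (4, 3)  # 4 prototypes x 3 treatments
        net.prototypes[...] = net.prototypes[0]  # collapse prototypes
        Y = net.prototype_outcome_matrix()
        assert np.allclose(Y, Y[0])  # identical prototypes, identical rows

    def test_combined_loss_gradients_match_finite_differences(self, rng):
        # the central correctness check for the whole training path,
        # on a 5-sample micro-batch covering every parameter tensor
        net = self.make(rng)
        X = rng.standard_normal((5, 6))
        y = rng.integers(0, 2, 5).astype(float)
        T = np.eye(3)[rng.integers(0, 3, 5)]
        args = (X, T, y, 0.01, 0.05, 0.85)
        loss, (L1, L2, L3), grads = net.loss_and_grads(*args)
        assert L2 >= 0.0 and L3 <= 0.0 and np.isfinite(loss)
        h = 1e-6
        for p, g in zip(net.params, grads):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = p[i]
                p[i] = orig + h
                up = net.loss_and_grads(*args)[0]
                p[i] = orig - h
                down = net.loss_and_grads(*args)[0]
                p[i] = orig
                fd = (up - down) / (2 * h)
                assert fd == pytest.approx(g[i], rel=1e-4, abs=1e-7)

    def test_euclidean_distance_variant_gradients(self, rng):
        net = self.make(rng, distance="euclidean")
        X = rng.standard_normal((4, 6))
        y = rng.integers(0, 2, 4).astype(float)
        T = np.eye(3)[rng.integers(0, 3, 4)]
        args = (X, T, y, 0.01, 0.05, 0.85)
        _, _, grads = net.loss_and_grads(*args)
        h = 1e-6
        p = net.prototypes
        g = grads[len(net.encoder.params) + len(net.decoder.params)]
        for i in [(0, 0), (1, 2), (3, 1)]:
            orig = p[i]
            p[i] = orig + h
            up = net.loss_and_grads(*args)[0]
            p[i] = orig - h
            down = net.loss_and_grads(*args)[0]
            p[i] = orig
            assert (up - down) / (2 * h) == pytest.approx(g[i], rel=1e-4, abs=1e-7)

    def test_one_adam_step_moves_prototypes(self, rng):
        # prototypes are trainable: one optimization step must change them
        net = self.make(rng)
        X = rng.standard_normal((5, 6))
        y = rng.integers(0, 2, 5).astype(float)
        T = np.eye(3)[rng.integers(0, 3, 5)]
        before = net.prototypes.copy()
        _, _, grads = net.loss_and_grads(X, T, y, 0.01, 0.05, 0.85)
        Adam(net.params, lr=1e-3).step(grads)
        assert not np.allclose(net.prototypes, before)
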