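"""KELM, ELM+ and KELM+ closed forms, their oracles and the LUPI contract."""

import numpy as np
import pytest

from kelmplus.errors import AlignmentError, InvalidInputError
from kelmplus.kelm import (decode_labels, encode_labels, predict_elm_plus, predict_kelm,
                           predict_kelm_plus, train_elm_plus, train_kelm,
                           train_kelm_plus)
from kelmplus.kernels import KernelSpec
from kelmplus.synthetic import generate_separable

LIN = KernelSpec("linear")


class TestLabelEncoding:
    def test_one_vs_all_matrix(self):
        T = encode_labels(np.array(["A", "B"]), ["A", "B"])
        np.testing.assert_array_equal(T, [[1, -1], [-1, 1]])

    def test_round_trip(self, rng):
        y = rng.choice(["A", "B", "C"], 30)
        T = encode_labels(y, ["A", "B", "C"])
        np.testing.assert_array_equal(decode_labels(T, ["A", "B", "C"]), y)

    def test_label_outside_order_rejected(self):
        with pytest.raises(InvalidInputError):
            encode_labels(np.array(["A", "D"]), ["A", "B"])

    def test_single_class_warns(self):
        with pytest.warns(UserWarning, match="one class"):
            T = encode_labels(np.array(["A", "A"]), ["A", "B"])
        assert T.shape == (2, 2)


class TestKELM:
    def test_scalar_closed_form(self):
        # n=1, linear kernel, x=[1], C=1: beta = (1/C + k11)^{-1} t = t/2
        model = train_kelm(np.array([[1.0]]), np.array([[3.0]]), 1.0, LIN)
        assert model.beta[0, 0] == pytest.approx(1.5)
        scores, _ = predict_kelm(model, np.array([[1.0]]))
        assert scores[0, 0] == pytest.approx(1.5)

    def test_ridge_limit_interpolates(self, rng):
        X = rng.standard_normal((10, 4))
        T = encode_labels(rng.integers(0, 2, 10), [0, 1])
        model = train_kelm(X, T, 1e9, KernelSpec("rbf", 0.5))
        scores, _ = predict_kelm(model, X)
        np.testing.assert_allclose(scores, T, atol=1e-4)

    def test_closed_form_vs_generic_solver(self, rng):
        from kelmplus.kernels import gram
        X = rng.standard_normal((15, 5))
        T = encode_labels(rng.integers(0, 3, 15), [0, 1, 2])
        C = 2.5
        spec = KernelSpec("rbf", 0.3)
        model = train_kelm(X, T, C, spec)
        beta_oracle = np.linalg.inv(gram(X, X, spec) + np.eye(15) / C) @ T
        np.testing.assert_allclose(model.beta, beta_oracle, atol=1e-8)

    def test_invalid_C_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            train_kelm(rng.standard_normal((3, 2)), np.ones((3, 2)), 0.0, LIN)

    def test_duplicated_test_row_duplicates_score(self, rng):
        X = rng.standard_normal((8, 3))
        model = train_kelm(X, encode_labels(rng.integers(0, 2, 8), [0, 1]), 1.0, LIN)
        Z = rng.standard_normal((1, 3))
        scores, _ = predict_kelm(model, np.vstack([Z, Z]))
        np.testing.assert_array_equal(scores[0], scores[1])

    def test_training_permutation_leaves_test_scores_unchanged(self, rng):
        X = rng.standard_normal((12, 4))
        y = rng.integers(0, 2, 12)
        Z = rng.standard_normal((5, 4))
        perm = rng.permutation(12)
        spec = KernelSpec("rbf", 0.6)
        s1, _ = predict_kelm(train_kelm(X, encode_labels(y, [0, 1]), 1.0, spec), Z)
        s2, _ = predict_kelm(train_kelm(X[perm], encode_labels(y[perm], [0, 1]), 1.0, spec), Z)
        np.testing.assert_allclose(s1, s2, atol=1e-10)


class TestELMPlus:
    def test_seeded_determinism(self, rng):
        X = rng.standard_normal((10, 3))
        P = rng.standard_normal((10, 5))
        T = encode_labels(rng.integers(0, 2, 10), [0, 1])
        m1 = train_elm_plus(X, P, T, 1.0, 1.0, L=20, L_tilde=15, seed=3)
        m2 = train_elm_plus(X, P, T, 1.0, 1.0, L=20, L_tilde=15, seed=3)
        np.testing.assert_array_equal(m1.beta, m2.beta)

    def test_kkt_linear_system_oracle(self, rng):
        X = rng.standard_normal((12, 4))
        P = rng.standard_normal((12, 6))
        T = encode_labels(rng.integers(0, 2, 12), [0, 1])
        C, eps = 2.0, 0.5
        model = train_elm_plus(X, P, T, C, eps, L=10, L_tilde=8, seed=1)
        # oracle: rebuild the hidden matrices, solve the stationarity system
        # (H~H~^T/eps + I/C) lambda = T - (C/eps) H~H~^T J via explicit inverse
        H = model.hidden_main(X)
        rng2 = np.random.default_rng(1)
        d = X.shape[1]
        _ = rng2.uniform(-1, 1, (d, 10)), rng2.uniform(-1, 1, 10)  # main map consumed
        Wp, bp = rng2.uniform(-1, 1, (P.shape[1], 8)), rng2.uniform(-1, 1, 8)
        Ht = 1.0 / (1.0 + np.exp(-(P @ Wp + bp)))
        G = Ht @ Ht.T
        J = np.ones_like(T)
        lam = np.linalg.inv(G / eps + np.eye(12) / C) @ (T - (C / eps) * G @ J)
        np.testing.assert_allclose(model.beta, H.T @ lam, atol=1e-6)

    def test_zero_privileged_hidden_reduces_to_CT(self, rng):
        X = rng.standard_normal((6, 3))
        T = encode_labels(rng.integers(0, 2, 6), [0, 1])
        C = 3.0
        model = train_elm_plus(X, np.zeros((6, 2)), T, C, 1.0, L=5, L_tilde=4, seed=0)
        # sigmoid(0 @ W + b) is constant per hidden unit, not zero; zero the
        # privileged Gram directly through the shared closed form instead
        from kelmplus.kelm import _lupi_weights
        H = model.hidden_main(X)
        beta = H.T @ _lupi_weights(np.zeros((6, 6)), T, C, 1.0)
        np.testing.assert_allclose(beta, H.T @ (C * T), atol=1e-10)


class TestKELMPlus:
    def test_scalar_closed_form(self):
        # n=m=1: beta = (omega/eps + 1/C)^{-1} (t - C*omega/eps)
        omega, t, C, eps = 4.0, 2.0, 1.5, 0.5
        X_priv = np.array([[2.0]])  # linear kernel: omega = 4
        model = train_kelm_plus(np.array([[1.0]]), X_priv, np.array([[t]]), C, eps, LIN, LIN)
        expected = (t - C * omega / eps) / (omega / eps + 1 / C)
        assert model.beta[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_zero_privileged_gram_gives_CT(self, rng):
        T = encode_labels(rng.integers(0, 2, 5), [0, 1])
        model = train_kelm_plus(rng.standard_normal((5, 3)), np.zeros((5, 2)), T,
                                2.0, 1.0, LIN, LIN)
        np.testing.assert_allclose(model.beta, 2.0 * T, atol=1e-10)

    def test_elm_plus_correspondence_oracle(self, rng):
        """KELM+ with linear kernels on the explicit hidden matrices equals ELM+."""
        X = rng.standard_normal((14, 4))
        P = rng.standard_normal((14, 6))
        y = rng.integers(0, 2, 14)
        T = encode_labels(y, [0, 1])
        Z = rng.standard_normal((6, 4))
        C, eps = 1.5, 0.8
        elm = train_elm_plus(X, P, T, C, eps, L=9, L_tilde=7, seed=5)
        H = elm.hidden_main(X)
        rng2 = np.random.default_rng(5)
        _ = rng2.uniform(-1, 1, (4, 9)), rng2.uniform(-1, 1, 9)
        Wp, bp = rng2.uniform(-1, 1, (6, 7)), rng2.uniform(-1, 1, 7)
        Ht = 1.0 / (1.0 + np.exp(-(P @ Wp + bp)))
        kelm_plus = train_kelm_plus(H, Ht, T, C, eps, LIN, LIN)
        s_kelm, _ = predict_kelm_plus(kelm_plus, elm.hidden_main(Z))
        s_elm, _ = predict_elm_plus(elm, Z)
        np.testing.assert_allclose(s_kelm, s_elm, atol=1e-6)

    def test_correspondence_holds_with_main_gram_variant(self, rng):
        X = rng.standard_normal((10, 3))
        P = rng.standard_normal((10, 4))
        T = encode_labels(rng.integers(0, 2, 10), [0, 1])
        Z = rng.standard_normal((4, 3))
        elm = train_elm_plus(X, P, T, 2.0, 1.0, L=6, L_tilde=5, seed=2,
                             include_main_gram=True)
        H = elm.hidden_main(X)
        rng2 = np.random.default_rng(2)
        _ = rng2.uniform(-1, 1, (3, 6)), rng2.uniform(-1, 1, 6)
        Wp, bp = rng2.uniform(-1, 1, (4, 5)), rng2.uniform(-1, 1, 5)
        Ht = 1.0 / (1.0 + np.exp(-(P @ Wp + bp)))
        km = train_kelm_plus(H, Ht, T, 2.0, 1.0, LIN, LIN, include_main_gram=True)
        np.testing.assert_allclose(predict_kelm_plus(km, elm.hidden_main(Z))[0],
                                   predict_elm_plus(elm, Z)[0], atol=1e-6)

    def test_misaligned_rows_rejected(self, rng):
        with pytest.raises(AlignmentError):
            train_kelm_plus(rng.standard_normal((5, 3)), rng.standard_normal((4, 2)),
                            np.ones((5, 2)), 1.0, 1.0, LIN, LIN)

    def test_privileged_data_never_consulted_at_test_time(self, rng):
        X = rng.standard_normal((10, 3))
        P = rng.standard_normal((10, 5))
        T = encode_labels(rng.integers(0, 2, 10), [0, 1])
        model = train_kelm_plus(X, P, T, 1.0, 1.0, KernelSpec("rbf", 0.5),
                                KernelSpec("rbf", 0.5))
        Z = rng.standard_normal((4, 3))
        s1, _ = predict_kelm_plus(model, Z)
        del P  # the model holds no reference to the privileged samples
        assert not any(arr.shape == (10, 5) for arr in vars(model).values()
                       if isinstance(arr, np.ndarray))
        s2, _ = predict_kelm_plus(model, Z)
        np.testing.assert_array_equal(s1, s2)

    def test_prediction_deterministic(self, rng):
        X = rng.standard_normal((8, 3))
        model = train_kelm_plus(X, rng.standard_normal((8, 4)),
                                encode_labels(rng.integers(0, 2, 8), [0, 1]),
                                1.0, 1.0, LIN, LIN)
        Z = rng.standard_normal((3, 3))
        np.testing.assert_array_equal(predict_kelm_plus(model, Z)[0],
                                      predict_kelm_plus(model, Z)[0])


class TestClosedFormsAgainstSolvers:
    def test_fifty_random_problems(self):
        """KELM and KELM+ closed forms match explicit-inverse solves to 1e-8."""
        from kelmplus.kernels import gram
        rng = np.random.default_rng(99)
        worst = 0.0
        for trial in range(50):
            n = int(rng.integers(3, 41))
            m = int(rng.integers(2, 4))
            d = int(rng.integers(2, 7))
            spec = KernelSpec("linear") if trial % 2 else KernelSpec("rbf", float(rng.uniform(0.1, 2)))
            X = rng.standard_normal((n, d))
            P = rng.standard_normal((n, d + 1))
            y = rng.integers(0, m, n)
            T = encode_labels(y, list(range(m)))
            C, eps = float(rng.uniform(0.1, 10)), float(rng.uniform(0.1, 10))
            K = gram(X, X, spec)
            G = gram(P, P, spec)
            beta_kelm = np.linalg.inv(K + np.eye(n) / C) @ T
            worst = max(worst, np.max(np.abs(train_kelm(X, T, C, spec).beta - beta_kelm)))
            J = np.ones_like(T)
            beta_plus = np.linalg.inv(G / eps + np.eye(n) / C) @ (T - (C / eps) * G @ J)
            model = train_kelm_plus(X, P, T, C, eps, spec, spec)
            worst = max(worst, np.max(np.abs(model.beta - beta_plus)))
        assert worst <= 1e-8

    def test_argmax_invariant_under_increasing_transform(self, rng):
        scores = rng.standard_normal((20, 3))
        a = decode_labels(scores, ["x", "y", "z"])
        b = decode_labels(3.0 * scores + 7.0, ["x", "y", "z"])  # strictly increasing
        np.testing.assert_array_equal(a, b)

    def test_separable_data_perfect_training_accuracy(self):
        X, y = generate_separable(20, 5, separation=10.0, seed=0)
        T = encode_labels(y, [0, 1])
        for train in (lambda: train_kelm(X, T, 100.0, KernelSpec("rbf", 0.2), classes=[0, 1]),):
            model = train()
            _, pred = predict_kelm(model, X)
            assert np.mean(pred == y) == 1.0
        plus = train_kelm_plus(X, X, T, 100.0, 1e6, KernelSpec("rbf", 0.2),
                               KernelSpec("rbf", 0.2), classes=[0, 1],
                               include_main_gram=True)
        _, pred = predict_kelm_plus(plus, X)
        assert np.mean(pred == y) == 1.0
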