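"""Recurrent cells, softmax head, classifiers and the training loop.

gru_step / lstm_step are checked against independent straight-from-the-
equations evaluators written with explicit per-unit loops.
"""

import math

import numpy as np
import pytest

from pcgscreen import models
from pcgscreen.autograd import softmax_cross_entropy


def _sig(v):
    return 1.0 / (1.0 + math.exp(-v))


def oracle_gru_step(x, h_prev, p):
    """Element-by-element evaluation of the GRU update equations."""
    H = h_prev.size
    h_new = np.empty(H)
    for i in range(H):
        z = _sig(p.b_z[i] + sum(p.U_z[j, i] * x[j] for j in range(x.size))
                 + sum(p.W_z[j, i] * h_prev[j] for j in range(H)))
        r_vec = [_sig(p.b_r[k] + sum(p.U_r[j, k] * x[j] for j in range(x.size))
                      + sum(p.W_r[j, k] * h_prev[j] for j in range(H)))
                 for k in range(H)]
        h_t = math.tanh(p.b_h[i] + sum(p.U_h[j, i] * x[j] for j in range(x.size))
                        + sum(p.W_h[j, i] * r_vec[j] * h_prev[j] for j in range(H)))
        h_new[i] = z * h_prev[i] + (1.0 - z) * h_t
    return h_new


def oracle_lstm_step(x, h_prev, s_prev, p, candidate="sigmoid"):
    H = h_prev.size
    h_new, s_new = np.empty(H), np.empty(H)
    squash = _sig if candidate == "sigmoid" else math.tanh
    for i in range(H):
        def gate(U, W, b):
            return _sig(b[i] + sum(U[j, i] * x[j] for j in range(x.size))
                        + sum(W[j, i] * h_prev[j] for j in range(H)))
        g = gate(p.U_g, p.W_g, p.b_g)
        f = gate(p.U_f, p.W_f, p.b_f)
        o = gate(p.U_o, p.W_o, p.b_o)
        cand = squash(p.b_c[i] + sum(p.U_c[j, i] * x[j] for j in range(x.size))
                      + sum(p.W_c[j, i] * h_prev[j] for j in range(H)))
        s_new[i] = f * s_prev[i] + g * cand
        h_new[i] = math.tanh(s_new[i]) * o
    return h_new, s_new


def _random_gru_params(rng, d, H):
    return models.GruLayerParams(*[rng.standard_normal(s) for s in
                                   [(d, H), (H, H), (H,)] * 3])


def _random_lstm_params(rng, d, H):
    return models.LstmLayerParams(*[rng.standard_normal(s) for s in
                                    [(d, H), (H, H), (H,)] * 4])


def test_gru_step_matches_equation_oracle():
    rng = np.random.default_rng(11)
    for _ in range(100):
        d, H = rng.integers(1, 4), rng.integers(1, 5)
        p = _random_gru_params(rng, d, H)
        x, h = rng.standard_normal(d), rng.uniform(-1, 1, H)
        np.testing.assert_allclose(models.gru_step(x, h, p),
                                   oracle_gru_step(x, h, p), atol=1e-12)


def test_lstm_step_matches_equation_oracle():
    rng = np.random.default_rng(12)
    for _ in range(100):
        d, H = rng.integers(1, 4), rng.integers(1, 5)
        p = _random_lstm_params(rng, d, H)
        x, h, s = rng.standard_normal(d), rng.uniform(-1, 1, H), rng.standard_normal(H)
        for cand in ("sigmoid", "tanh"):
            got_h, got_s = models.lstm_step(x, h, s, p, candidate=cand)
            exp_h, exp_s = oracle_lstm_step(x, h, s, p, candidate=cand)
            np.testing.assert_allclose(got_h, exp_h, atol=1e-12)
            np.testing.assert_allclose(got_s, exp_s, atol=1e-12)


def test_gru_update_gate_one_freezes_state():
    rng = np.random.default_rng(13)
    p = _random_gru_params(rng, 2, 3)
    p.b_z[:] = 500.0  # z -> 1
    p.U_z[:] = p.W_z[:] = 0.0
    h = rng.uniform(-1, 1, 3)
    np.testing.assert_allclose(models.gru_step(rng.standard_normal(2), h, p), h)


def test_gru_gates_zero_reduce_to_feedforward():
    rng = np.random.default_rng(14)
    p = _random_gru_params(rng, 2, 3)
    p.b_z[:] = p.b_r[:] = -500.0  # z -> 0, r -> 0
    p.U_z[:] = p.W_z[:] = p.U_r[:] = p.W_r[:] = 0.0
    x, h = rng.standard_normal(2), rng.uniform(-1, 1, 3)
    np.testing.assert_allclose(models.gru_step(x, h, p),
                               np.tanh(p.b_h + x @ p.U_h), atol=1e-12)


def test_lstm_forget_one_input_zero_keeps_cell():
    rng = np.random.default_rng(15)
    p = _random_lstm_params(rng, 2, 3)
    p.b_f[:] = 500.0
    p.U_f[:] = p.W_f[:] = 0.0
    p.b_g[:] = -500.0
    p.U_g[:] = p.W_g[:] = 0.0
    s = rng.standard_normal(3)
    _, s_new = models.lstm_step(rng.standard_normal(2), rng.uniform(-1, 1, 3), s, p)
    np.testing.assert_allclose(s_new, s, atol=1e-12)
    p.b_o[:] = -500.0  # o -> 0 silences the output
    p.U_o[:] = p.W_o[:] = 0.0
    h_new, _ = models.lstm_step(rng.standard_normal(2), rng.uniform(-1, 1, 3), s, p)
    np.testing.assert_allclose(h_new, 0.0, atol=1e-12)


def test_gru_hidden_state_stays_bounded():
    """h is a convex combination of h_prev and tanh output, so |h| <= 1."""
    rng = np.random.default_rng(16)
    p = _random_gru_params(rng, 1, 6)
    h = np.zeros(6)
    for t in range(200):
        h = models.gru_step(rng.standard_normal(1) * 5, h, p)
        assert np.all(np.abs(h) <= 1.0)


def test_softmax_properties():
    np.testing.assert_allclose(models.softmax([0.0, 0.0, 0.0]), [1 / 3] * 3)
    a = models.softmax([1.0, 2.0, 3.0])
    b = models.softmax([101.0, 102.0, 103.0])
    np.testing.assert_allclose(a, b, atol=1e-12)  # shift invariance
    big = models.softmax([1000.0, 0.0, 0.0])
    assert np.isfinite(big).all() and big[0] == pytest.approx(1.0)
    rng = np.random.default_rng(17)
    batch = models.softmax(rng.standard_normal((20, 3)))
    np.testing.assert_allclose(batch.sum(axis=1), 1.0, atol=1e-6)
    assert (batch > 0).all()


def test_build_model_head_and_output():
    for name in ("gru", "lstm", "fcn"):
        m = models.build_model(name, models.TrainConfig(n_layers=1, units=8,
                                                        chunk_size=10))
        assert m.n_output_units == 3
        probs = m.predict_proba(np.random.default_rng(0).random((4, 960)))
        assert probs.shape == (4, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_models_accept_both_frame_lengths():
    m = models.build_model("gru", models.TrainConfig(n_layers=1, units=8,
                                                     chunk_size=10))
    for L in (480, 960):  # 0.8 s and 1.6 s at 600 Hz
        probs = m.predict_proba(np.zeros((2, L)))
        assert probs.shape == (2, 3)


def test_chunk_mismatch_error_names_dimensions():
    m = models.build_model("gru", models.TrainConfig(n_layers=1, units=4,
                                                     chunk_size=7))
    with pytest.raises(ValueError, match="not divisible by chunk size 7"):
        m.forward(np.zeros((2, 960)))


def _separable_frames(rng, n=60, L=40):
    """Three classes encoded by disjoint mean levels; linearly separable."""
    y = np.arange(n) % 3
    X = rng.normal(0, 0.05, (n, L)) + y[:, None] * 1.0
    return X, y


def test_training_reaches_perfect_accuracy_on_separable_data(rng):
    X, y = _separable_frames(rng)
    cfg = models.TrainConfig(epochs=50, n_layers=1, units=8, chunk_size=4,
                             batch_size=8, rng_seed=3)
    m = models.build_model("gru", cfg)
    hist = models.train(m, X, y, None, None, cfg)
    assert max(hist["train_acc"]) == 1.0


def test_initial_loss_is_log_three_on_balanced_classes(rng):
    X, y = _separable_frames(rng)
    cfg = models.TrainConfig(epochs=1, n_layers=1, units=8, chunk_size=4, rng_seed=0)
    m = models.build_model("gru", cfg)
    hist = models.train(m, X, y, None, None, cfg)
    assert hist["loss"][0] == pytest.approx(np.log(3), abs=0.2)


def test_l2_regularization_shrinks_weight_norm(rng):
    X, y = _separable_frames(rng)

    def norm_after(lam):
        cfg = models.TrainConfig(epochs=10, n_layers=1, units=8, chunk_size=4,
                                 rng_seed=5, l2_lambda=lam)
        m = models.build_model("gru", cfg)
        models.train(m, X, y, None, None, cfg)
        return sum(float(np.sum(w.data**2)) for w in m.weights())

    assert norm_after(0.01) < norm_after(0.0)


def test_training_reproducible_under_fixed_seed(rng):
    X, y = _separable_frames(rng)
    losses = []
    for _ in range(2):
        cfg = models.TrainConfig(epochs=1, n_layers=1, units=8, chunk_size=4,
                                 rng_seed=7)
        m = models.build_model("gru", cfg)
        losses.append(models.train(m, X, y, None, None, cfg)["loss"][0])
    assert losses[0] == losses[1]


def test_train_input_validation(rng):
    cfg = models.TrainConfig(epochs=1, n_layers=1, units=4, chunk_size=4)
    m = models.build_model("gru", cfg)
    with pytest.raises(ValueError, match="empty"):
        models.train(m, np.empty((0, 8)), np.empty(0, int), None, None, cfg)
    with pytest.raises(ValueError, match="labels"):
        models.train(m, np.zeros((4, 8)), np.array([0, 1, 2, 5]), None, None, cfg)


def test_predict_deterministic(rng, small_dataset):
    m = models.build_model("gru", models.TrainConfig(n_layers=1, units=8,
                                                     chunk_size=10))
    X = small_dataset.X()[:8]
    p1, l1 = models.predict(m, X)
    p2, l2 = models.predict(m, X)
    np.testing.assert_array_equal(p1, p2)
    np.testing.assert_array_equal(l1, l2)


def test_classifier_gradients_match_finite_differences(rng):
    """Backprop through the fused GRU/LSTM/FCN graphs vs central differences."""
    X = rng.standard_normal((4, 20))
    y = rng.integers(0, 3, 4)
    for name in ("gru", "lstm", "fcn"):
        cfg = models.TrainConfig(n_layers=2, units=4, chunk_size=5, rng_seed=1)
        m = models.build_model(name, cfg)
        loss = softmax_cross_entropy(m.forward(X, train=True), y)
        loss.backward()
        p = m.weights()[0]
        eps = 1e-2  # float32 graph: wide stencil, loose tolerance
        orig = float(p.data.flat[0])
        p.data.flat[0] = orig + eps
        lp = float(softmax_cross_entropy(m.forward(X, train=True), y).data)
        p.data.flat[0] = orig - eps
        lm = float(softmax_cross_entropy(m.forward(X, train=True), y).data)
        p.data.flat[0] = orig
        fd = (lp - lm) / (2 * eps)
        assert p.grad.flat[0] == pytest.approx(fd, abs=2e-2), name
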