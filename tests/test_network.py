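import numpy as np
import pytest

import pulsegrip.network as net
from pulsegrip.network import (
    Bottleneck,
    CNNLSTM,
    ModelConfig,
    bottleneck_forward,
    build_model,
    forward,
)
from pulsegrip.training import _batch_loss_and_grad, _one_hot

TINY = ModelConfig(
    input_length=64, n_classes=2, cnn_stem_channels=8,
    bottleneck_channels=(4, 4, 8), lstm_hidden_1=6, lstm_out=4,
)


def _conv_same_oracle(x, W, b):
    """Direct correlation with symmetric zero padding (loop reference)."""
    c_out, c_in, k = W.shape
    B, _, T = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
    y = np.zeros((B, c_out, T))
    for o in range(c_out):
        for c in range(c_in):
            for j in range(k):
                y[:, o, :] += W[o, c, j] * xp[:, c, j : j + T]
        y[:, o, :] += b[o]
    return y


class TestBuildModel:
    def test_final_layer_width_is_n_classes(self):
        for n in (2, 3, 6):
            cfg = ModelConfig(**{**TINY.__dict__, "n_classes": n})
            m = build_model(cfg)
            assert m.fc.W.v.shape[1] == n
            assert m.spec.n_classes == n

    def test_default_lstm_path_outputs_20_values(self):
        m = build_model(ModelConfig(n_classes=2))
        assert m.spec.lstm_path_width == 20
        assert m.config.lstm_hidden_1 == 64

    def test_parameter_count_is_pure_function_of_config(self):
        a = build_model(TINY, seed=0)
        b = build_model(TINY, seed=99)
        assert a.n_parameters == b.n_parameters > 0

    def test_too_short_input_rejected_with_minimum(self):
        with pytest.raises(ValueError, match="minimum"):
            ModelConfig(**{**TINY.__dict__, "input_length": 16})

    def test_third_lstm_flag_adds_parameters(self):
        a = build_model(TINY)
        b = build_model(ModelConfig(**{**TINY.__dict__, "third_lstm": True}))
        assert b.n_parameters > a.n_parameters


class TestBottleneck:
    def test_zero_weights_give_zero_output(self, rng):
        block = Bottleneck(np.random.default_rng(0), 8, (4, 4, 8), "b")
        for p in block.params:
            p.v[...] = 0
        x = rng.normal(size=(2, 8, 30)).astype(np.float32)
        assert np.all(bottleneck_forward(x, block) == 0)

    def test_temporal_length_preserved(self, rng):
        block = Bottleneck(np.random.default_rng(0), 8, (4, 4, 8), "b")
        for T in (3, 7, 30):
            x = rng.normal(size=(2, 8, T)).astype(np.float32)
            assert bottleneck_forward(x, block).shape == (2, 8, T)

    def test_zero_trunk_reduces_to_relu_of_branch(self, rng):
        block = Bottleneck(np.random.default_rng(1), 8, (4, 4, 8), "b")
        for layer in block.trunk:
            if hasattr(layer, "W"):
                layer.W.v[...] = 0
                layer.b.v[...] = 0
        x = rng.normal(size=(2, 8, 25)).astype(np.float32)
        got = bottleneck_forward(x, block)
        # oracle: run the branch convolutions directly
        h = x.astype(float)
        for i, layer in enumerate(block.branch):
            if hasattr(layer, "W"):
                k = layer.k
                W = layer.W.v.reshape(layer.c_out, layer.c_in, k).astype(float)
                h = _conv_same_oracle(h, W, layer.b.v.astype(float))
            else:
                h = np.maximum(h, 0.0)
        expected = np.maximum(h, 0.0)
        np.testing.assert_allclose(got, expected, rtol=1e-4, atol=1e-5)

    def test_channel_mismatch_rejected(self, rng):
        block = Bottleneck(np.random.default_rng(0), 8, (4, 4, 8), "b")
        with pytest.raises(ValueError, match="channels"):
            bottleneck_forward(rng.normal(size=(2, 5, 30)), block)


class TestForward:
    def test_scores_in_unit_interval(self, rng):
        m = build_model(TINY, seed=1)
        x = rng.normal(size=(4, 64)).astype(np.float32)
        s = forward(m, x)
        assert s.shape == (4, 2)
        assert np.all((s >= 0) & (s <= 1))

    def test_batch_invariance_in_eval_mode(self, rng):
        m = build_model(TINY, seed=1)
        x = rng.normal(size=(6, 64)).astype(np.float32)
        full = forward(m, x)
        single = forward(m, x[2:3])
        np.testing.assert_allclose(full[2], single[0], atol=1e-6)

    def test_seeded_init_reproducible(self, rng):
        x = rng.normal(size=(3, 64)).astype(np.float32)
        a = forward(build_model(TINY, seed=5), x)
        b = forward(build_model(TINY, seed=5), x)
        assert np.array_equal(a, b)

    def test_eval_mode_deterministic_despite_dropout(self, rng):
        m = build_model(TINY, seed=2)
        x = rng.normal(size=(3, 64)).astype(np.float32)
        assert np.array_equal(forward(m, x), forward(m, x))

    def test_wrong_length_rejected(self, rng):
        m = build_model(TINY, seed=0)
        with pytest.raises(ValueError, match="expected batch"):
            forward(m, rng.normal(size=(2, 32)))


class TestBackprop:
    def test_gradients_match_finite_differences(self, monkeypatch, rng):
        """Whole-model analytic gradients vs central differences (float64)."""
        monkeypatch.setattr(net, "_F32", np.float64)
        cfg = ModelConfig(**{**TINY.__dict__, "dropout_cnn": 0.0,
                             "dropout_lstm": 0.0})
        m = build_model(cfg, seed=0)
        for _, bn in m._named_bn():
            bn.momentum = 0.0
        # nudge biases off zero: exact-zero ReLU kinks make the analytic
        # subgradient and the symmetric difference legitimately disagree
        nudge = np.random.default_rng(3)
        for p in m.parameters():
            if p.name.endswith(".b"):
                p.v += nudge.normal(0, 1e-3, p.v.shape)
        x = rng.normal(size=(4, 64))
        y = _one_hot(np.array([0, 1, 0, 1]), 2)
        _, dz = _batch_loss_and_grad(m, x, y, "bce")
        m.zero_grad()
        m.backward(dz)
        pick = np.random.default_rng(2)
        for p in m.parameters():
            flat = p.v.ravel()
            for idx in pick.choice(flat.size, size=min(3, flat.size),
                                   replace=False):
                old = flat[idx]
                eps = 1e-6
                flat[idx] = old + eps
                lp, _ = _batch_loss_and_grad(m, x, y, "bce")
                flat[idx] = old - eps
                lm, _ = _batch_loss_and_grad(m, x, y, "bce")
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = p.g.ravel()[idx]
                assert num == pytest.approx(ana, rel=1e-3, abs=1e-7), p.name

    def test_state_dict_round_trip(self, rng):
        m = build_model(TINY, seed=0)
        x = rng.normal(size=(2, 64)).astype(np.float32)
        before = forward(m, x)
        state = m.state_dict()
        m2 = build_model(TINY, seed=77)
        m2.load_state_dict(state)
        np.testing.assert_allclose(forward(m2, x), before, atol=1e-7)
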