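"""Network forward/backward correctness: closed forms, gradient check, training."""

import zlib

import numpy as np
import pytest

from mcnn_ner.encoding import Vocab, aux_encode
from mcnn_ner.model import (
    Batch,
    ModelConfig,
    OutputScores,
    char_repr,
    forward,
    forward_batch,
    init_params,
    label_probs,
    load_model,
    log_likelihood,
    loss_and_grads,
    fit,
    pack_batch,
    predict_labels,
    save_model,
)

from conftest import random_instance


@pytest.fixture
def tiny_setup(tiny_vocab, tiny_config):
    rng = np.random.default_rng(0)
    params = init_params(tiny_config, tiny_vocab)
    # move every parameter off the ReLU/max-pool kinks that the zeroed PAD
    # rows would otherwise sit on (gradients are undefined exactly there)
    for k in params:
        params[k] = params[k] + rng.normal(0, 0.1, params[k].shape)
    batch = pack_batch(
        [random_instance(rng, tiny_vocab) for _ in range(4)],
        min_char_len=tiny_config.char_cnn_window,
    )
    return params, tiny_config, batch


class TestConfig:
    def test_defaults_are_published_values(self):
        c = ModelConfig()
        assert (c.window, c.word_dim, c.char_dim, c.lex_dim) == (13, 200, 20, 5)
        assert (c.char_cnn_window, c.char_cnn_filters) == (3, 20)
        assert (c.word_conv_window, c.word_conv_filters) == (3, 100)
        assert c.n_conv_layers == 3
        assert c.input_dim == 225

    def test_flatten_length_700_for_3_layers(self):
        assert ModelConfig(n_conv_layers=3).flat_dim == 700

    def test_flatten_length_4_layers(self):
        assert ModelConfig(n_conv_layers=4).flat_dim == 500

    def test_deep_stack_shape_arithmetic(self):
        assert ModelConfig(n_conv_layers=5).conv_out_positions == 3
        with pytest.raises(ValueError):
            ModelConfig(n_conv_layers=7)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(window=12)


class TestCharRepr:
    def test_all_pad_zero_filters_gives_zero_vector(self, tiny_vocab, tiny_config):
        params = init_params(tiny_config, tiny_vocab)
        params["char_W"][:] = 0.0
        params["char_b"][:] = 0.0
        out = char_repr([0, 0, 0], params, tiny_config)
        np.testing.assert_array_equal(out, np.zeros(tiny_config.char_cnn_filters))

    @pytest.mark.parametrize("length", [1, 2, 3, 7])
    def test_output_length_is_filter_count(self, tiny_vocab, tiny_config, length):
        params = init_params(tiny_config, tiny_vocab)
        out = char_repr(list(range(min(length, 3))) * 3, params, tiny_config)
        assert out.shape == (tiny_config.char_cnn_filters,)

    def test_single_position_pool_is_identity(self, tiny_vocab, tiny_config):
        """A word of exactly window-size chars yields one conv position; the
        max-pool passes it through."""
        params = init_params(tiny_config, tiny_vocab)
        chars = [2, 3, 4]
        C = params["char_emb"][np.asarray(chars)].reshape(-1)
        expected = np.maximum(C @ params["char_W"].T + params["char_b"], 0.0)
        np.testing.assert_allclose(char_repr(chars, params, tiny_config), expected)

    def test_empty_sequence_errors(self, tiny_vocab, tiny_config):
        with pytest.raises(ValueError):
            char_repr([], init_params(tiny_config, tiny_vocab), tiny_config)


class TestForward:
    def test_zero_heads_give_zero_scores(self, tiny_vocab, tiny_config):
        params = init_params(tiny_config, tiny_vocab)
        for key in ("main_W", "main_b", "aux_W", "aux_b"):
            params[key][:] = 0.0
        rng = np.random.default_rng(1)
        scores = forward(random_instance(rng, tiny_vocab), params, tiny_config)
        np.testing.assert_array_equal(scores.out_main, np.zeros(3))
        np.testing.assert_array_equal(scores.out_aux, np.zeros(9))

    def test_deterministic_in_eval_mode(self, tiny_setup):
        params, config, batch = tiny_setup
        m1, a1, _ = forward_batch(params, config, batch)
        m2, a2, _ = forward_batch(params, config, batch)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(a1, a2)

    def test_default_dims_flatten_to_700(self, tiny_vocab):
        config = ModelConfig(dropout_rate=0.0, dtype="float64")
        params = init_params(config, tiny_vocab)
        rng = np.random.default_rng(2)
        batch = pack_batch([random_instance(rng, tiny_vocab, window=13)], min_char_len=3)
        _, _, cache = forward_batch(params, config, batch, want_cache=True)
        assert cache["flat"].shape == (1, 700)


class TestLabelProbs:
    def test_uniform_scores(self):
        p_main, p_aux = label_probs(OutputScores(np.zeros(3), np.zeros(9)))
        np.testing.assert_allclose(p_main, np.full(3, 1 / 3))
        np.testing.assert_allclose(p_aux, np.full(9, 1 / 9))

    def test_closed_form(self):
        p_main, _ = label_probs(OutputScores(np.array([np.log(2), 0.0, 0.0]), None))
        np.testing.assert_allclose(p_main, [0.5, 0.25, 0.25])

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=3)
        a = rng.normal(size=9)
        p1 = label_probs(OutputScores(s, a))
        p2 = label_probs(OutputScores(s + 123.4, a - 55.5))
        np.testing.assert_allclose(p1[0], p2[0], atol=1e-12)
        np.testing.assert_allclose(p1[1], p2[1], atol=1e-12)

    def test_sums_to_one_within_1e9(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            p_main, p_aux = label_probs(
                OutputScores(rng.normal(scale=30, size=3), rng.normal(scale=30, size=9))
            )
            assert abs(p_main.sum() - 1) < 1e-9
            assert abs(p_aux.sum() - 1) < 1e-9
            assert (p_main >= 0).all() and (p_aux >= 0).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            label_probs(OutputScores(np.array([np.nan, 0, 0]), None))


class TestLogLikelihood:
    def test_uniform_model_closed_form(self, tiny_vocab, tiny_config):
        """Zero-weight heads: per-instance J = ln(1/3) + ln(1/9)."""
        params = init_params(tiny_config, tiny_vocab)
        for key in ("main_W", "main_b", "aux_W", "aux_b"):
            params[key][:] = 0.0
        rng = np.random.default_rng(5)
        instances = [random_instance(rng, tiny_vocab) for _ in range(7)]
        J = log_likelihood(instances, params, tiny_config)
        np.testing.assert_allclose(J, 7 * (np.log(1 / 3) + np.log(1 / 9)), rtol=1e-12)

    def test_additivity(self, tiny_setup):
        params, config, _ = tiny_setup
        rng = np.random.default_rng(6)
        vocab = Vocab()
        for w in ["alpha", "beta", "gamma", "delta"]:
            vocab.add_word(w)
        for ch in "abgdxyz":
            vocab.add_char(ch)
        A = [random_instance(rng, vocab) for _ in range(3)]
        B = [random_instance(rng, vocab) for _ in range(4)]
        JA = log_likelihood(A, params, config)
        JB = log_likelihood(B, params, config)
        JAB = log_likelihood(A + B, params, config)
        np.testing.assert_allclose(JAB, JA + JB, rtol=1e-9)

    def test_mls_off_reduces_to_plain_cross_entropy(self, tiny_vocab):
        """Dropping the auxiliary term of the objective leaves exactly the
        3-way cross-entropy of the main head."""
        from dataclasses import replace

        cfg_mls = ModelConfig(
            window=5, word_dim=6, char_dim=4, char_cnn_filters=2, word_conv_filters=3,
            n_conv_layers=1, lex_dim=2, dropout_rate=0.0, dtype="float64", seed=0,
        )
        cfg_plain = replace(cfg_mls, use_mls=False)
        params = init_params(cfg_mls, tiny_vocab)
        params_plain = {k: v for k, v in params.items() if not k.startswith("aux")}
        rng = np.random.default_rng(7)
        instances = [random_instance(rng, tiny_vocab) for _ in range(5)]
        batch = pack_batch(instances, min_char_len=3)
        loss_plain, _ = loss_and_grads(params_plain, cfg_plain, batch)
        # manual main-head cross-entropy
        out_main, _, _ = forward_batch(params, cfg_mls, batch)
        manual = 0.0
        for i, inst in enumerate(instances):
            p, _ = label_probs(OutputScores(out_main[i], None))
            manual -= np.log(p[inst.y])
        np.testing.assert_allclose(loss_plain, manual, rtol=1e-9)


class TestGradients:
    def test_analytic_matches_central_differences(self, tiny_setup):
        """Max relative error of every sampled partial derivative < 1e-4."""
        params, config, batch = tiny_setup
        _, grads = loss_and_grads(params, config, batch)
        eps = 1e-6
        max_rel = 0.0
        for key, arr in params.items():
            r = np.random.default_rng(zlib.crc32(key.encode()))
            for fi in r.choice(arr.size, size=min(25, arr.size), replace=False):
                mi = np.unravel_index(fi, arr.shape)
                orig = arr[mi]
                arr[mi] = orig + eps
                lp, _ = loss_and_grads(params, config, batch)
                arr[mi] = orig - eps
                lm, _ = loss_and_grads(params, config, batch)
                arr[mi] = orig
                num = (lp - lm) / (2 * eps)
                rel = abs(num - grads[key][mi]) / max(abs(num), abs(grads[key][mi]), 1e-8)
                max_rel = max(max_rel, rel)
        assert max_rel < 1e-4

    def test_pair_mode_gradients(self, tiny_vocab):
        cfg = ModelConfig(
            window=5, word_dim=4, char_dim=3, char_cnn_filters=2, word_conv_filters=2,
            n_conv_layers=1, lex_dim=2, dropout_rate=0.0, dtype="float64",
            aux_mode="pair", seed=0,
        )
        rng = np.random.default_rng(8)
        params = init_params(cfg, tiny_vocab)
        for k in params:
            params[k] = params[k] + rng.normal(0, 0.1, params[k].shape)
        batch = pack_batch([random_instance(rng, tiny_vocab) for _ in range(3)], min_char_len=3)
        _, grads = loss_and_grads(params, cfg, batch)
        eps = 1e-6
        for key in ("prev_W", "next_b", "conv0_W", "word_emb"):
            arr = params[key]
            fi = arr.size // 2
            mi = np.unravel_index(fi, arr.shape)
            orig = arr[mi]
            arr[mi] = orig + eps
            lp, _ = loss_and_grads(params, cfg, batch)
            arr[mi] = orig - eps
            lm, _ = loss_and_grads(params, cfg, batch)
            arr[mi] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - grads[key][mi]) <= 1e-4 * max(abs(num), 1e-4)


class TestTraining:
    def _fixture(self, tiny_vocab):
        rng = np.random.default_rng(9)
        return [random_instance(rng, tiny_vocab) for _ in range(10)]

    def test_one_epoch_decreases_loss(self, tiny_vocab, tiny_config):
        from dataclasses import replace

        instances = self._fixture(tiny_vocab)
        cfg = replace(tiny_config, epochs=1, batch_size=5, learning_rate=0.05)
        batch = pack_batch(instances, min_char_len=3)
        params0 = init_params(cfg, tiny_vocab)
        loss0, _ = loss_and_grads(params0, cfg, batch)
        params1 = fit(instances, cfg, tiny_vocab)
        loss1, _ = loss_and_grads(params1, cfg, batch)
        assert loss1 < loss0

    def test_same_seed_identical_params(self, tiny_vocab, tiny_config):
        from dataclasses import replace

        instances = self._fixture(tiny_vocab)
        cfg = replace(tiny_config, epochs=2, batch_size=4, dropout_rate=0.3)
        p1 = fit(instances, cfg, tiny_vocab)
        p2 = fit(instances, cfg, tiny_vocab)
        for key in p1:
            np.testing.assert_array_equal(p1[key], p2[key])

    def test_empty_training_set_rejected(self, tiny_vocab, tiny_config):
        with pytest.raises(ValueError):
            fit([], tiny_config, tiny_vocab)


class TestPredict:
    def test_zero_model_ties_resolve_to_O(self, tiny_vocab, tiny_config):
        params = init_params(tiny_config, tiny_vocab)
        params["main_W"][:] = 0.0
        params["main_b"][:] = 0.0
        rng = np.random.default_rng(10)
        instances = [random_instance(rng, tiny_vocab) for _ in range(6)]
        assert predict_labels(instances, params, tiny_config) == ["O"] * 6

    def test_output_length_matches(self, tiny_setup, tiny_vocab):
        params, config, _ = tiny_setup
        rng = np.random.default_rng(11)
        instances = [random_instance(rng, tiny_vocab) for _ in range(9)]
        assert len(predict_labels(instances, params, config)) == 9


class TestCheckpoint:
    def test_round_trip(self, tmp_path, tiny_vocab, tiny_config):
        params = init_params(tiny_config, tiny_vocab)
        path = tmp_path / "model.npz"
        save_model(path, params, tiny_config, tiny_vocab)
        p2, cfg2, vocab2 = load_model(path)
        assert cfg2 == tiny_config
        assert vocab2.word_to_id == tiny_vocab.word_to_id
        for key in params:
            np.testing.assert_array_equal(params[key], p2[key])
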