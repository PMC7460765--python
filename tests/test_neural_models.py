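"""Seq2seq mechanics: shapes, causality, decoding, checkpoints, training."""

import numpy as np
import pytest

from chemnmt.corpus import (
    NamePair,
    ParallelCorpus,
    build_vocabulary,
    encode_batch,
)
from chemnmt import neural_models as nn
from chemnmt import _autodiff as ad


@pytest.fixture(scope="module")
def toy_corpus():
    pairs = [
        NamePair("ab", "XY"),
        NamePair("ba", "YX"),
        NamePair("aab", "XXY"),
        NamePair("abb", "XYY"),
    ]
    return ParallelCorpus(pairs)


@pytest.fixture(scope="module")
def toy_vocab(toy_corpus):
    return build_vocabulary(toy_corpus)


def _softmax(z):
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class TestBuild:
    def test_lstm_state_width_is_latent_dim(self, toy_vocab):
        cfg = nn.TrainConfig(latent_dim=32, seed=0)
        model = nn.build_lstm_translator(toy_vocab, cfg)
        h, c = nn._lstm_encode(model, np.zeros((3, 5), dtype=np.int32) + toy_vocab.source_index("a"))
        assert h.shape == (3, 32) and c.shape == (3, 32)

    def test_seeded_init_reproducible(self, toy_vocab):
        cfg = nn.TrainConfig(latent_dim=16, seed=5)
        a = nn.build_lstm_translator(toy_vocab, cfg)
        b = nn.build_lstm_translator(toy_vocab, cfg)
        for k in a.params:
            assert (a.params[k].data == b.params[k].data).all()

    def test_cnn_layer_counts(self, toy_vocab):
        """Three encoder, three target-side and two output convolutions."""
        model = nn.build_cnn_translator(toy_vocab, nn.TrainConfig(latent_dim=16))
        conv_names = [k for k in model.params if k.endswith("_W") and "conv" in k]
        assert sum(k.startswith("enc_conv") for k in conv_names) == 3
        assert sum(k.startswith("dec_conv") for k in conv_names) == 3
        assert sum(k.startswith("post_conv") for k in conv_names) == 2

    def test_untrained_output_distribution_normalized(self, toy_corpus, toy_vocab):
        model = nn.build_cnn_translator(toy_vocab, nn.TrainConfig(latent_dim=16, seed=2))
        batch = encode_batch(toy_corpus.pairs, toy_vocab, 4, 4)
        enc_out, mask = nn._cnn_encode(model, batch.encoder_input)
        logits = nn._cnn_decode_logits(model, enc_out, mask, batch.decoder_input).data
        probs = _softmax(logits)
        assert probs.shape[-1] == toy_vocab.n_target
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_bad_latent_dim(self):
        with pytest.raises(ValueError):
            nn.TrainConfig(latent_dim=0)


class TestCausality:
    def test_target_perturbation_cannot_reach_past_outputs(self, toy_vocab):
        """Changing the decoder input at step t leaves outputs at steps < t
        unchanged (causal convolutions on the target side).  A target
        character perturbed at step t enters the decoder at step t+1 via
        the start-symbol shift, so no output at or before t can move."""
        model = nn.build_cnn_translator(toy_vocab, nn.TrainConfig(latent_dim=24, seed=3))
        rng = np.random.default_rng(0)
        enc = rng.integers(0, toy_vocab.n_source - 3, size=(2, 6)).astype(np.int32)
        dec = rng.integers(0, toy_vocab.n_target - 3, size=(2, 8)).astype(np.int32)
        enc_out, mask = nn._cnn_encode(model, enc)
        base = nn._cnn_decode_logits(model, enc_out, mask, dec).data
        for t in range(8):
            pert = dec.copy()
            pert[:, t] = (pert[:, t] + 1) % (toy_vocab.n_target - 3)
            out = nn._cnn_decode_logits(model, enc_out, mask, pert).data
            assert np.allclose(out[:, :t, :], base[:, :t, :], atol=1e-6)
            # and the perturbation is visible from step t onward
            assert not np.allclose(out[:, t:, :], base[:, t:, :], atol=1e-6)


class TestTraining:
    def test_zero_epochs_is_identity(self, toy_corpus, toy_vocab):
        cfg = nn.TrainConfig(epochs=0, latent_dim=16, seed=0)
        model = nn.build_lstm_translator(toy_vocab, cfg)
        before = {k: t.data.copy() for k, t in model.params.items()}
        nn.train(model, toy_corpus, cfg)
        assert model.history == []
        for k in before:
            assert (model.params[k].data == before[k]).all()

    def test_oov_in_corpus_fails_before_training(self, toy_vocab):
        bad = ParallelCorpus([NamePair("zz", "XY")])
        cfg = nn.TrainConfig(epochs=1, latent_dim=16)
        model = nn.build_lstm_translator(toy_vocab, cfg)
        before = {k: t.data.copy() for k, t in model.params.items()}
        from chemnmt.corpus import OOVError

        with pytest.raises(OOVError):
            nn.train(model, bad, cfg)
        for k in before:
            assert (model.params[k].data == before[k]).all()

    def test_history_records_loss_and_accuracy(self, toy_corpus, toy_vocab):
        cfg = nn.TrainConfig(
            epochs=3, batch_size=4, latent_dim=16, seed=0, validation_fraction=0.0
        )
        model = nn.build_lstm_translator(toy_vocab, cfg)
        nn.train(model, toy_corpus, cfg)
        assert [h["epoch"] for h in model.history] == [1, 2, 3]
        assert all(0 <= h["accuracy"] <= 1 for h in model.history)


class TestTranslate:
    def test_oov_input_is_failure_value(self, toy_vocab):
        model = nn.build_lstm_translator(toy_vocab, nn.TrainConfig(latent_dim=16))
        res = nn.translate(model, "aΩb")
        assert not res.succeeded
        assert res.failure_reason == "oov_character"
        assert res.output is None

    def test_untrained_model_still_produces_output(self, toy_vocab):
        model = nn.build_cnn_translator(toy_vocab, nn.TrainConfig(latent_dim=16, seed=1))
        model.max_target_len = 4
        res = nn.translate(model, "ab")
        assert res.succeeded and isinstance(res.output, str)

    def test_termination_bound(self, toy_vocab):
        model = nn.build_lstm_translator(toy_vocab, nn.TrainConfig(latent_dim=16, seed=1))
        res = nn.translate(model, "ab", max_output_len=5)
        assert res.succeeded and len(res.output) <= 5


class TestMemorization:
    """Both architectures, trained to convergence on ten pairs, must
    reproduce every stored target by greedy decoding."""

    @pytest.mark.parametrize("arch", ["LSTM", "CNN"])
    def test_reproduces_all_targets(self, memorized_models, tiny_corpus, arch):
        model = memorized_models[arch]
        results = nn.translate_many(model, [p.source_name for p in tiny_corpus])
        assert all(r.succeeded for r in results)
        assert [r.output for r in results] == [p.target_name for p in tiny_corpus]


class TestCheckpoint:
    def test_save_load_prediction_identical(self, memorized_models, tiny_corpus, tmp_path):
        model = memorized_models["LSTM"]
        nn.save_checkpoint(model, tmp_path / "ckpt")
        loaded = nn.load_checkpoint(tmp_path / "ckpt")
        names = [p.source_name for p in tiny_corpus]
        assert [r.output for r in nn.translate_many(loaded, names)] == [
            r.output for r in nn.translate_many(model, names)
        ]
        for k in model.params:
            assert (loaded.params[k].data == model.params[k].data).all()
        assert loaded.history[-1]["accuracy"] == pytest.approx(
            model.history[-1]["accuracy"]
        )


class TestAutodiffGradients:
    """Finite-difference check of the engine's composite ops."""

    @pytest.mark.parametrize("padding", ["same", "causal"])
    def test_conv1d_gradients(self, padding):
        rng = np.random.default_rng(0)
        x = ad.parameter(rng.normal(size=(2, 5, 3)).astype(np.float32))
        w = ad.parameter(rng.normal(size=(3, 3, 4)).astype(np.float32) * 0.3)
        b = ad.parameter(np.zeros(4, dtype=np.float32))
        mask = np.ones((2 * 5,), dtype=np.float32)
        tgt = rng.integers(0, 4, size=10)

        def loss_value():
            out = ad.conv1d(x, w, b, padding)
            flat = ad.reshape(out, (10, 4))
            loss, _ = ad.softmax_cross_entropy(flat, tgt, mask)
            return loss

        loss = loss_value()
        loss.backward()
        eps = 1e-3
        for tensor in (x, w):
            flat_data = tensor.data.ravel()
            grad = tensor.grad.ravel()
            for idx in (0, len(flat_data) // 2, len(flat_data) - 1):
                orig = flat_data[idx]
                flat_data[idx] = orig + eps
                up = float(loss_value().data)
                flat_data[idx] = orig - eps
                down = float(loss_value().data)
                flat_data[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert numeric == pytest.approx(float(grad[idx]), abs=2e-2)
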