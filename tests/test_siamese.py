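"""Spectrogram preprocessing, pair sampling and twin-encoder training."""

import numpy as np
import pytest

import croaker as ck
from croaker.siamese import (
    EmbeddingNet,
    SpectrogramConfig,
    TrainConfig,
    TrainHistory,
    db_to_unit,
    split_dataset,
)
from croaker.trains import default_ipi_model, default_spl_model, draw_train


@pytest.fixture(scope="module")
def spect_cfg():
    return SpectrogramConfig(out_size=(64, 64), nperseg=256)


@pytest.fixture(scope="module")
def chain_spectrograms(mother, reference_spec, spect_cfg):
    """Small two-class dataset: 2-pulse vs 9-pulse trains."""
    pulse = ck.synthesize_call(reference_spec, mother).peak_normalized()
    pulse = ck.Waveform(pulse.samples, pulse.fs, "uPa")
    rng = np.random.default_rng(42)
    ipi_m, spl_m = default_ipi_model(), default_spl_model()
    data = {}
    for chain in (2, 9):
        items = []
        for _ in range(12):
            tr = draw_train(pulse, chain, ipi_m, spl_m, rng)
            w = tr.assembled.peak_normalized()
            # rescale into the dB display range of the spectrogram map
            w = ck.Waveform(w.samples * 10 ** (110 / 20), w.fs, "uPa")
            items.append(ck.make_spectrogram(w, SpectrogramConfig(
                out_size=(64, 64), nperseg=256)))
        data[chain] = items
    return data


class TestSpectrogram:
    def test_db_mapping_endpoints_and_midpoint(self):
        cfg = SpectrogramConfig()
        assert db_to_unit(np.array([60.0]), cfg)[0] == 0.0
        assert db_to_unit(np.array([120.0]), cfg)[0] == 1.0
        assert db_to_unit(np.array([90.0]), cfg)[0] == 0.5
        assert db_to_unit(np.array([30.0]), cfg)[0] == 0.0  # clipped

    def test_output_shape_and_range(self, reference_call, spect_cfg):
        img = ck.make_spectrogram(reference_call, spect_cfg)
        assert img.shape == (64, 64)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_tone_brightest_row(self, spect_cfg):
        fs = 48000.0
        t = np.arange(48000) / fs
        level = 10 ** (110 / 20)  # within the 60-120 dB display range
        w = ck.Waveform(level * np.sin(2 * np.pi * 500 * t), fs, "uPa")
        img = ck.make_spectrogram(w, spect_cfg)
        row = np.argmax(img.sum(axis=1))
        # 64 rows cover 0..24 kHz -> 500 Hz lands near row 1-2
        expected = 500.0 / (fs / 2) * 63
        assert abs(row - expected) <= 2

    def test_too_short_input_rejected(self, spect_cfg):
        with pytest.raises(ValueError, match="shorter"):
            ck.make_spectrogram(ck.Waveform(np.zeros(100), 48000.0),
                                spect_cfg)


class TestPairs:
    def test_balanced_labels_and_determinism(self, chain_spectrograms):
        rng = np.random.default_rng(3)
        pairs = ck.sample_pairs(chain_spectrograms, 100, rng)
        labels = [p.label for p in pairs]
        assert labels.count(0) == 50 and labels.count(1) == 50
        rng2 = np.random.default_rng(3)
        pairs2 = ck.sample_pairs(chain_spectrograms, 100, rng2)
        assert all(np.array_equal(a.spectrogram_a, b.spectrogram_a)
                   for a, b in zip(pairs, pairs2))

    def test_single_class_rejected(self, chain_spectrograms):
        only = {2: chain_spectrograms[2]}
        with pytest.raises(ValueError, match="two chain classes"):
            ck.sample_pairs(only, 10, np.random.default_rng(0))


class TestContrastiveLoss:
    def test_positive_pair_at_zero_distance(self):
        assert ck.contrastive_loss(0.0, 0) == 0.0

    def test_negative_pair_beyond_margin(self):
        assert ck.contrastive_loss(0.35, 1, margin=0.3) == 0.0

    def test_negative_pair_at_zero_distance_is_margin_squared(self):
        assert ck.contrastive_loss(0.0, 1, margin=0.3) == \
            pytest.approx(0.09)

    def test_nonnegative(self, rng):
        d = rng.random(100)
        y = rng.integers(0, 2, 100)
        assert np.all(ck.contrastive_loss(d, y) >= 0)


class TestEmbeddingNet:
    def test_cosine_self_similarity_is_one(self, rng):
        net = EmbeddingNet((64, 64), embed_dim=32, hidden=(32,), pool=8)
        x = rng.random((3, 64, 64))
        e = net.forward(x)
        assert np.allclose(ck.cosine_similarity(e, e), 1.0)

    def test_default_embedding_width(self):
        net = EmbeddingNet((224, 224))
        assert net.embed_dim == 512
        assert net.n_parameters > 0
        assert "512" in net.architecture

    def test_gradient_matches_finite_differences(self, rng):
        """Hand-derived backprop against numerical differentiation."""
        from croaker.siamese import PairSample, _pair_loss_and_grads

        net = EmbeddingNet((16, 16), embed_dim=8, hidden=(12,), pool=4,
                           seed=0)
        pairs = [PairSample(rng.random((16, 16)), rng.random((16, 16)), y)
                 for y in (0, 1, 0)]
        loss, gw, gb, _, _ = _pair_loss_and_grads(net, pairs, 0.3)
        eps = 1e-6
        for li in range(len(net.weights)):
            idx = (0, 0)
            net.weights[li][idx] += eps
            lp, *_ = _pair_loss_and_grads(net, pairs, 0.3)
            net.weights[li][idx] -= 2 * eps
            lm, *_ = _pair_loss_and_grads(net, pairs, 0.3)
            net.weights[li][idx] += eps
            num = (lp - lm) / (2 * eps)
            assert gw[li][idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestTraining:
    def test_split_is_disjoint(self, chain_spectrograms):
        rng = np.random.default_rng(0)
        train, val = split_dataset(chain_spectrograms, 0.7, rng)
        for c in train:
            ids_t = {id(x) for x in train[c]}
            ids_v = {id(x) for x in val.get(c, [])}
            assert not ids_t & ids_v

    def test_zero_learning_rate_keeps_history_flat(self, chain_spectrograms):
        cfg = TrainConfig(learning_rate=0.0, batch=8, max_steps=60,
                          eval_every=20, embed_dim=16, hidden=(16,),
                          pool=8, seed=0)
        _, hist = ck.train_siamese(chain_spectrograms, cfg)
        assert len(set(np.round(hist.val_loss, 12))) == 1

    def test_seed_determinism(self, chain_spectrograms):
        cfg = TrainConfig(learning_rate=1e-3, batch=8, max_steps=40,
                          eval_every=20, embed_dim=16, hidden=(16,),
                          pool=8, seed=5)
        _, h1 = ck.train_siamese(chain_spectrograms, cfg)
        _, h2 = ck.train_siamese(chain_spectrograms, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_separability_on_held_out(self, chain_spectrograms):
        """After short training, held-out positive pairs are closer than
        negative pairs in the embedding space."""
        cfg = TrainConfig(learning_rate=1e-3, batch=16, max_steps=400,
                          eval_every=100, embed_dim=32, hidden=(64,),
                          pool=4, seed=1)
        _, hist = ck.train_siamese(chain_spectrograms, cfg)
        assert hist.val_pos_cos[-1] > hist.val_neg_cos[-1]

    def test_evaluate_identical_sets(self, chain_spectrograms):
        net = EmbeddingNet((64, 64), embed_dim=16, hidden=(16,), pool=8)
        frame = ck.evaluate_similarity(net, chain_spectrograms,
                                       chain_spectrograms)
        sims = frame[frame.chain != "average"].cosine_similarity
        assert np.allclose(sims, 1.0)

    def test_random_model_similarity_in_range(self, chain_spectrograms):
        net = EmbeddingNet((64, 64), embed_dim=16, hidden=(16,), pool=8,
                           seed=9)
        frame = ck.evaluate_similarity(net, {2: chain_spectrograms[2]},
                                       {2: chain_spectrograms[9][:12]})
        v = frame.cosine_similarity.iloc[0]
        assert -1.0 <= v <= 1.0
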