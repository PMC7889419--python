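"""Architecture trace, index scaling, scoring interface and training contracts."""

import numpy as np
import pytest

import scindex
from scindex import nn
from scindex.errors import (ConfigError, DegenerateLabelsError,
                            InvalidParameterError, LeakageError)
from scindex.model import _build_layers, _forward_eval


class TestArchitecture:
    def test_spatial_trace_and_flatten_width(self):
        cfg = scindex.CNNConfig()
        assert cfg.spatial_trace() == [124, 62, 31, 15]
        assert cfg.flatten_width() == 15 * 15 * 128

    def test_shape_probe_through_real_layers(self):
        layers = _build_layers(scindex.CNNConfig(), np.random.default_rng(0))
        h = np.zeros((1, 124, 124, 1), dtype=np.float32)
        spatial = []
        for layer in layers:
            h = layer.forward(h, train=False)
            if isinstance(layer, nn.MaxPool2D):
                spatial.append(h.shape[1])
        assert spatial == [62, 31, 15]
        assert h.shape == (1, 2)

    def test_channel_counts(self):
        layers = _build_layers(scindex.CNNConfig(), np.random.default_rng(0))
        convs = [l for l in layers if isinstance(l, nn.Conv2D)]
        assert [c.c_out for c in convs] == [32, 64, 128]

    def test_bad_trace_rejected_with_trace_in_message(self):
        cfg = scindex.CNNConfig(conv_filters=(32, 64))
        with pytest.raises(ConfigError, match=r"124, 62, 31"):
            cfg.validate()

    def test_unsupported_variants_rejected(self):
        with pytest.raises(ConfigError):
            scindex.CNNConfig(conv_padding="valid")
        with pytest.raises(ConfigError):
            scindex.CNNConfig(pool_size=3)


class TestIndex:
    @pytest.mark.parametrize("p, expected", [(0.0, 0.0), (1.0, 100.0),
                                             (0.5, 50.0), (0.657, 65.7)])
    def test_index_is_100_times_pain_probability(self, p, expected):
        assert scindex.compute_index(p) == pytest.approx(expected)

    def test_out_of_range_probability_rejected(self):
        for bad in (-0.01, 1.01):
            with pytest.raises(InvalidParameterError):
                scindex.compute_index(bad)

    def test_series_invariants(self):
        s = scindex.PainIndexSeries(values=[10.0, 20.0, 60.0],
                                    start_times_s=[0.0, 10.0, 20.0])
        assert s.mean_index == pytest.approx(30.0)
        with pytest.raises(InvalidParameterError):
            scindex.PainIndexSeries(values=[101.0], start_times_s=[0.0])


class TestScoring:
    def test_probabilities_sum_to_one(self, tiny_trained):
        x = np.random.default_rng(0).random((50, 124, 124), dtype=np.float32)
        p = tiny_trained.predict_proba(x)
        assert p.shape == (50, 2)
        assert np.all((p >= 0) & (p <= 1))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_inference_deterministic(self, tiny_trained):
        x = np.random.default_rng(1).random((8, 124, 124), dtype=np.float32)
        np.testing.assert_array_equal(tiny_trained.predict_proba(x),
                                      tiny_trained.predict_proba(x))

    def test_zeroed_output_layer_gives_even_odds(self, tiny_trained):
        final = tiny_trained.layers[-1]
        saved = {k: v.copy() for k, v in final.params.items()}
        try:
            for v in final.params.values():
                v[...] = 0.0
            p = tiny_trained.predict_proba(
                np.random.default_rng(2).random((5, 124, 124), dtype=np.float32))
            np.testing.assert_allclose(p, 0.5, atol=1e-6)
        finally:
            for k, v in saved.items():
                final.params[k][...] = v

    def test_wrong_patch_shape_rejected(self, tiny_trained):
        with pytest.raises(ConfigError):
            tiny_trained.predict_proba(np.zeros((3, 64, 64), dtype=np.float32))

    def test_score_recording_five_minutes_gives_30_values(self, tiny_trained):
        params = scindex.SynthCohortParams(n_subjects=1, duration_s=300.0, seed=3)
        rec = scindex.generate_cohort(params)[0]
        series = tiny_trained.score_recording(rec)
        assert series.values.size == 30
        assert np.all((series.values >= 0) & (series.values <= 100))
        assert series.mean_index == pytest.approx(series.values.mean())

    def test_summary_mentions_architecture(self, tiny_trained):
        text = tiny_trained.summary()
        assert "124 -> 62 -> 31 -> 15" in text
        assert "28,800" in text


class TestTraining:
    def _data(self, n=48):
        rng = np.random.default_rng(7)
        x = rng.random((n, 124, 124), dtype=np.float32)
        y = np.tile([0, 1], n // 2)
        x[y == 1, 40:60, :] += 0.5
        return x, y

    def test_single_class_labels_rejected(self):
        x, _ = self._data(8)
        model = scindex.SpectrogramCNN(x, np.zeros(8, dtype=int))
        with pytest.raises(DegenerateLabelsError):
            model.fit(scindex.TrainConfig(max_epochs=1))

    def test_subject_overlap_rejected(self):
        x, y = self._data(8)
        subjects = np.array(["A", "A", "B", "B", "C", "C", "D", "D"])
        model = scindex.SpectrogramCNN(x, y, subject_ids=subjects)
        with pytest.raises(LeakageError):
            model.fit(scindex.TrainConfig(max_epochs=1),
                      validation=(x[:2], y[:2], subjects[:2]))

    def test_seeded_training_reproducible(self):
        x, y = self._data(16)
        tc = scindex.TrainConfig(max_epochs=1, seed=5)
        res_a = scindex.SpectrogramCNN(x, y).fit(tc)
        res_b = scindex.SpectrogramCNN(x, y).fit(tc)
        probe = x[:4]
        np.testing.assert_array_equal(res_a.predict_proba(probe),
                                      res_b.predict_proba(probe))
        assert res_a.history == res_b.history

    def test_training_loss_decreases_over_best_epoch_prefix(self, learning_runs):
        # optimisation sanity: on the separable cohort the training loss
        # improves from the first epoch to the selected best epoch in
        # >= 90% of the seeded runs
        ok = 0
        for run in learning_runs:
            losses = run["history"]["train_loss"][:run["best_epoch"] + 1]
            if losses[-1] <= losses[0]:
                ok += 1
        assert ok >= len(learning_runs) * 0.9

    def test_functional_wrappers(self):
        x, y = self._data(16)
        model = scindex.build_model()
        res = scindex.train_model(model, x, y,
                                  train_config=scindex.TrainConfig(max_epochs=1))
        p = scindex.predict_proba(res, x[0])
        assert p.shape == (1, 2)


class TestPersistence:
    def test_checkpoint_round_trip(self, tiny_trained, tmp_path):
        path = tmp_path / "model.npz"
        tiny_trained.stft_config_hash = "stfthash"
        tiny_trained.save(path)
        loaded = scindex.SpectrogramCNNResults.load(path)
        x = np.random.default_rng(4).random((6, 124, 124), dtype=np.float32)
        np.testing.assert_allclose(loaded.predict_proba(x),
                                   tiny_trained.predict_proba(x), atol=1e-6)
        assert loaded.best_epoch == tiny_trained.best_epoch

    def test_checkpoint_refuses_other_stft_config(self, tiny_trained, tmp_path):
        path = tmp_path / "model.npz"
        tiny_trained.stft_config_hash = "stfthash"
        tiny_trained.save(path)
        with pytest.raises(ConfigError):
            scindex.SpectrogramCNNResults.load(path, expected_stft_hash="other")
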