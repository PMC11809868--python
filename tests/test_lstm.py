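"""LSTM detector: normalization, schedule, training behaviour, prediction."""

from dataclasses import replace

import numpy as np
import pytest

from gaitmark.encoding import curve_correlation, encode_events
from gaitmark.io import SignalChannel
from gaitmark.lstm import (GaitLSTM, ModelConfig, TrainingSequence,
                           build_training_sequences, learning_rate_at,
                           normalize_input, predict_curves, train_incremental)
from gaitmark.nn import LSTMCore
from gaitmark.simulate import SimParams, simulate_trial

TINY = ModelConfig(hidden_units=8, minibatch=4, epochs_per_increment=30,
                   chunk_length_samples=200, chunk_overlap_samples=40, seed=3)


@pytest.fixture(scope="module")
def short_clean_trial():
    p = SimParams(duration_s=20.0, rate_hz=100.0, noise_sd_N=0.0,
                  heel_noise_sd_mm=0.0, seed=17)
    return simulate_trial(p)


class TestNormalize:
    def test_grf_in_body_weight_units(self):
        ch = SignalChannel(np.array([0.0, 350.0, 700.0]), 100.0, "grf_vertical")
        out = normalize_input(ch, 700.0)
        np.testing.assert_allclose(out.values, [0.0, 0.5, 1.0])

    def test_heel_min_max_scaled(self):
        ch = SignalChannel(np.array([10.0, 60.0, 110.0]), 100.0, "heel_height")
        out = normalize_input(ch, 700.0)
        np.testing.assert_allclose(out.values, [0.0, 0.5, 1.0])

    def test_constant_heel_maps_to_zeros(self):
        ch = SignalChannel(np.full(10, 42.0), 100.0, "heel_height")
        out = normalize_input(ch, 700.0)
        np.testing.assert_array_equal(out.values, np.zeros(10))

    def test_nonpositive_body_weight_rejected(self):
        ch = SignalChannel(np.zeros(5), 100.0, "grf_vertical")
        with pytest.raises(ValueError):
            normalize_input(ch, 0.0)


class TestSchedule:
    def test_learning_rate_closed_form(self):
        cfg = ModelConfig(initial_learning_rate=1e-3, decay_factor=0.5,
                          decay_every_epochs=50)
        assert learning_rate_at(cfg, 120) == pytest.approx(1e-3 * 0.25)
        for e in range(500):
            expected = 1e-3 * 0.5 ** (e // 50)
            assert learning_rate_at(cfg, e) == pytest.approx(expected)

    def test_sequences_built_in_left_right_order(self, short_clean_trial):
        from gaitmark.io import preprocess_trial

        trial, truth = short_clean_trial
        trial = preprocess_trial(trial, target_rate_hz=100.0)
        seqs = build_training_sequences([trial, trial], [truth, truth], "igrf")
        assert [s.label[-1] for s in seqs] == ["L", "R", "L", "R"]

    def test_mismatched_lengths_rejected(self):
        ch = SignalChannel(np.zeros(100), 100.0, "grf_vertical")
        c9 = encode_events(
            __import__("gaitmark").GaitEventSet((), source="truth"), 90, 100.0)
        c100 = encode_events(
            __import__("gaitmark").GaitEventSet((), source="truth"), 100, 100.0)
        with pytest.raises(ValueError):
            TrainingSequence(ch, c9, c100)


def _tiny_sequences(trial, truth, kind="igrf", n=1):
    from gaitmark.io import preprocess_trial

    trial = preprocess_trial(trial, target_rate_hz=100.0)
    return build_training_sequences([trial] * n, [truth] * n, kind)


class TestTraining:
    def test_loss_decreases_on_fixed_seed(self, short_clean_trial):
        trial, truth = short_clean_trial
        seqs = _tiny_sequences(trial, truth)[:1]
        _, hist = train_incremental(TINY, seqs)
        assert hist[0][-1] < hist[0][0]

    def test_deterministic_history_for_fixed_seed(self, short_clean_trial):
        trial, truth = short_clean_trial
        seqs = _tiny_sequences(trial, truth)[:1]
        cfg = replace(TINY, epochs_per_increment=5)
        _, h1 = train_incremental(cfg, seqs)
        _, h2 = train_incremental(cfg, seqs)
        assert h1 == h2  # bitwise identical

    def test_overfits_one_short_sequence(self, short_clean_trial):
        """Capacity check: a small model fitted to one clean sequence
        reproduces its target curves almost exactly."""
        trial, truth = short_clean_trial
        seqs = _tiny_sequences(trial, truth)[:1]
        cfg = ModelConfig(hidden_units=24, minibatch=8, epochs_per_increment=200,
                          chunk_length_samples=400, chunk_overlap_samples=200,
                          initial_learning_rate=3e-3, seed=5)
        model, _ = train_incremental(cfg, seqs)
        hs, to = predict_curves(model, seqs[0].input, "L")
        assert curve_correlation(hs, seqs[0].target_hs) > 0.95
        assert curve_correlation(to, seqs[0].target_to) > 0.95

    def test_empty_sequence_list_rejected(self):
        with pytest.raises(ValueError):
            train_incremental(TINY, [])


class TestPrediction:
    def test_output_length_and_finiteness_untrained(self):
        model = GaitLSTM.initialise(TINY)
        ch = SignalChannel(np.linspace(0, 1, 537), 100.0, "grf_vertical")
        hs, to = predict_curves(model, ch)
        assert len(hs) == len(to) == 537
        assert np.all(np.isfinite(hs.values))

    def test_zero_length_input_rejected(self):
        model = GaitLSTM.initialise(TINY)
        ch = SignalChannel(np.zeros(2), 100.0, "grf_vertical")
        object.__setattr__(ch, "values", np.zeros(0))
        with pytest.raises(ValueError):
            predict_curves(model, ch)

    def test_chunked_prediction_matches_whole_outside_warmup(self, short_clean_trial):
        """Stitched per-chunk outputs agree with single-pass prediction
        except within each chunk's warm-up window."""
        trial, truth = short_clean_trial
        seqs = _tiny_sequences(trial, truth)[:1]
        model, _ = train_incremental(replace(TINY, epochs_per_increment=10), seqs)
        x = seqs[0].input
        whole_hs, _ = predict_curves(model, x, chunk_length=len(x), chunk_overlap=0)
        L, V = 500, 250
        chunk_hs, _ = predict_curves(model, x, chunk_length=L, chunk_overlap=V)
        diff = np.abs(whole_hs.values - chunk_hs.values)
        assert np.max(diff) < 0.15  # warm-up transients are bounded
        # outside warm-up regions the curves agree tightly
        stride = L - V
        mask = np.ones(len(x), bool)
        for s in range(stride, len(x) - L + 1, stride):
            mask[s + V - 50 : s + V + 50] = False
        assert np.max(diff[mask]) < 0.05

    def test_checkpoint_round_trip(self, short_clean_trial, tmp_path):
        trial, truth = short_clean_trial
        seqs = _tiny_sequences(trial, truth)[:1]
        model, _ = train_incremental(replace(TINY, epochs_per_increment=3), seqs)
        path = tmp_path / "model.npz"
        model.save(path)
        back = GaitLSTM.load(path)
        assert back.config == model.config
        h1, _ = predict_curves(model, seqs[0].input)
        h2, _ = predict_curves(back, seqs[0].input)
        np.testing.assert_array_equal(h1.values, h2.values)


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        """BPTT gradients agree with central finite differences."""
        core = LSTMCore(1, 5, 2, rng)
        x = rng.normal(size=(2, 7, 1))
        target = rng.normal(size=(2, 7, 2))

        def loss():
            y, _ = core.forward(x)
            return float(np.mean((y - target) ** 2))

        y, cache = core.forward(x, want_cache=True)
        dy = 2.0 * (y - target) / y.size
        grads = core.backward(cache, dy)
        eps = 1e-6
        for name in ("Wx", "Wh", "b", "Wy", "by"):
            p = core.params[name]
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                assert grads[name].reshape(-1)[idx] == pytest.approx(fd, rel=1e-4, abs=1e-9)
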