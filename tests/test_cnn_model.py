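import numpy as np
import pytest

from pcgnet.cnn_model import (
    CNN1D,
    ModelConfig,
    build_model,
    forward,
    load_checkpoint,
    save_checkpoint,
    softmax,
)
from pcgnet.errors import ValidationError
from pcgnet.segment_augment import Segment

# a narrow configuration for fast unit tests; same code paths as the default
SMALL = ModelConfig(
    input_len=64,
    conv_filters=(4, 6),
    kernel_size=3,
    pool_size=2,
    conv_dropout=0.25,
    dense_units=8,
    dense_dropout=0.5,
    seed=11,
)


class TestModelConfig:
    def test_default_flatten_arithmetic_8s_input(self):
        cfg = ModelConfig(input_len=16_000)
        assert cfg.final_time_steps == 250  # 16,000 / 2**6
        assert cfg.flatten_len == 250 * 16

    def test_flatten_arithmetic_4s_input(self):
        cfg = ModelConfig(input_len=8_000)
        assert cfg.final_time_steps == 125

    def test_indivisible_input_rejected_with_arithmetic(self):
        cfg = ModelConfig(input_len=1_000)
        with pytest.raises(ValidationError, match="64"):
            cfg.validate()

    def test_bad_head_rejected(self):
        with pytest.raises(ValidationError):
            ModelConfig(input_len=64, conv_filters=(4,), head="linear").validate()


class TestSoftmax:
    def test_symmetry(self):
        np.testing.assert_allclose(softmax(np.array([0.0, 0.0])), [0.5, 0.5])

    def test_constant_logits_uniform(self):
        for c in (-1000.0, 0.0, 777.0):
            np.testing.assert_allclose(softmax(np.array([c, c, c])), np.ones(3) / 3)

    def test_closed_form(self):
        np.testing.assert_allclose(
            softmax(np.array([np.log(1.0), np.log(3.0)])), [0.25, 0.75], atol=1e-12
        )

    def test_shift_invariance_and_stability(self):
        logits = np.array([[1e4, 1e4 + 1.0]])
        p = softmax(logits)
        assert np.all(np.isfinite(p))
        np.testing.assert_allclose(p, softmax(logits - 1e4), atol=1e-12)


def _segments(n, length=64, fs=2000.0, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    return [
        Segment(samples=rng.standard_normal(length), fs=fs,
                label="abnormal" if i % 2 else "normal", source_id=f"s{i}")
        for i in range(n)
    ]


class TestForward:
    def test_softmax_head_rows_sum_to_one(self):
        model = build_model(SMALL)
        probs = forward(model, _segments(8))
        assert probs.shape == (8, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs > 0.0) and np.all(probs < 1.0)

    def test_sigmoid_head_in_open_interval(self):
        from dataclasses import replace

        model = build_model(replace(SMALL, head="sigmoid1"))
        probs = forward(model, _segments(8))
        assert probs.shape == (8, 1)
        assert np.all(probs > 0.0) and np.all(probs < 1.0)

    def test_probability_validity_many_random_inputs(self):
        from dataclasses import replace

        x = np.random.default_rng(3).standard_normal((1000, 64)).astype(np.float32)
        probs = build_model(SMALL).net.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        p1 = build_model(replace(SMALL, head="sigmoid1")).net.predict_proba(x)
        assert np.all(p1 > 0.0) and np.all(p1 < 1.0)

    def test_duplicated_segment_gives_identical_rows(self):
        model = build_model(SMALL)
        seg = _segments(1)[0]
        probs = forward(model, [seg, seg.copy(), seg])
        np.testing.assert_array_equal(probs[0], probs[1])
        np.testing.assert_array_equal(probs[0], probs[2])

    def test_inference_deterministic(self):
        model = build_model(SMALL)
        segs = _segments(16)
        a = forward(model, segs)
        b = forward(model, segs)
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_length_mismatch_names_both_lengths(self):
        model = build_model(SMALL)
        bad = _segments(1, length=32)
        with pytest.raises(ValidationError, match="64") as err:
            forward(model, bad)
        assert "32" in str(err.value)

    def test_seeded_init_reproducible(self):
        a = build_model(SMALL)
        b = build_model(SMALL)
        for (i, n, pa), (_, _, pb) in zip(a.net.parameters(), b.net.parameters()):
            np.testing.assert_array_equal(pa, pb)


class TestShapeAlgebra:
    def test_time_axis_halves_at_each_block(self):
        model = build_model(SMALL)
        x = np.random.default_rng(0).standard_normal((2, 64, 1)).astype(np.float32)
        h = x
        lengths = []
        for layer in model.net.layers:
            h = layer.forward(h, False)
            if type(layer).__name__ == "_MaxPool":
                lengths.append(h.shape[1])
        assert lengths == [64 // 2, 64 // 4]


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = build_model(SMALL)
        model.training_history = [{"epoch": 0, "train_loss": 1.0, "train_acc": 0.5,
                                   "val_loss": 1.0, "val_acc": 0.5}]
        segs = _segments(4)
        before = forward(model, segs)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert back.config == model.config
        assert back.training_history == model.training_history
        np.testing.assert_array_equal(forward(back, segs), before)
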