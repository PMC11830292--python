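import numpy as np
import pytest

from pcgnet.errors import ValidationError
from pcgnet.segment_augment import (
    DEFAULT_PITCH_FACTOR,
    LabeledDataset,
    Segment,
    balance_classes,
    pad_segment,
    pitch_shift,
    segment_signal,
)
from pcgnet.signal_io import AudioSignal, fft_peak_hz

from conftest import make_dataset, make_sine


def _signal(seconds, fs=2000, label="normal"):
    rng = np.random.default_rng(7)
    return AudioSignal(samples=rng.standard_normal(int(seconds * fs)), fs=fs,
                       label=label, source_id="rec")


class TestSegmentSignal:
    def test_exact_tiling(self):
        segs = segment_signal(_signal(8.0), seg_seconds=4.0, overlap_frac=0.0)
        assert len(segs) == 2
        assert all(s.samples.size == 8000 for s in segs)
        assert [s.start_s for s in segs] == [0.0, 4.0]

    def test_trailing_partial_window_padded(self):
        sig = _signal(10.0)
        segs = segment_signal(sig, seg_seconds=4.0, overlap_frac=0.0)
        assert len(segs) == 3  # ceil((10-4)/4) + 1
        assert all(s.samples.size == 8000 for s in segs)
        # third window holds 2 s of real audio then wraps
        np.testing.assert_array_equal(segs[2].samples[:4000], sig.samples[16000:])
        np.testing.assert_array_equal(segs[2].samples[4000:8000], sig.samples[16000:])

    def test_half_overlap_start_times(self):
        segs = segment_signal(_signal(10.0), seg_seconds=4.0, overlap_frac=0.5)
        assert [s.start_s for s in segs] == [0.0, 2.0, 4.0, 6.0]

    def test_label_inherited(self):
        segs = segment_signal(_signal(8.0, label="abnormal"), 4.0, 0.0)
        assert all(s.label == "abnormal" for s in segs)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValidationError):
            segment_signal(_signal(8.0), 4.0, 1.0)

    def test_lossless_tiling_reconstruction(self):
        sig = _signal(12.0)
        segs = segment_signal(sig, seg_seconds=4.0, overlap_frac=0.0)
        rebuilt = np.concatenate([s.samples for s in segs])
        np.testing.assert_array_equal(rebuilt, sig.samples)

    def test_short_signal_yields_one_padded_segment(self):
        segs = segment_signal(_signal(1.5), seg_seconds=4.0, overlap_frac=0.0)
        assert len(segs) == 1
        assert segs[0].samples.size == 8000


class TestPadSegment:
    def test_wrap_repeats_cyclically(self):
        np.testing.assert_array_equal(
            pad_segment([1, 2, 3], 7, mode="wrap"), [1, 2, 3, 1, 2, 3, 1]
        )

    def test_zero_appends_silence(self):
        np.testing.assert_array_equal(
            pad_segment([1, 2, 3], 5, mode="zero"), [1, 2, 3, 0, 0]
        )

    @pytest.mark.parametrize("mode", ["wrap", "zero"])
    def test_already_full_is_identity(self, mode):
        np.testing.assert_array_equal(pad_segment([1.0, 2.0], 2, mode=mode), [1.0, 2.0])

    def test_overlong_input_rejected(self):
        with pytest.raises(ValidationError):
            pad_segment([1, 2, 3], 2, mode="wrap")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            pad_segment([1, 2], 4, mode="reflect")


class TestPitchShift:
    def _tone_segment(self, freq, fs=2000, seconds=4.0):
        sig = make_sine(freq, fs=fs, seconds=seconds, label="normal")
        return Segment(samples=sig.samples, fs=fs, label="normal", source_id="t")

    def test_identity_factor(self):
        seg = self._tone_segment(100.0)
        out = pitch_shift(seg, 1.0)
        assert np.sqrt(np.mean((out.samples - seg.samples) ** 2)) < 1e-3
        assert out.augmented

    def test_tone_moves_by_factor(self):
        seg = self._tone_segment(100.0)
        out = pitch_shift(seg, 1.23)
        assert out.samples.size == seg.samples.size
        bin_hz = seg.fs / seg.samples.size
        assert abs(fft_peak_hz(out.samples, out.fs) - 123.0) <= bin_hz

    def test_default_factor_maps_band_edge(self):
        # the default ratio stretches the 60-650 Hz band up to 60-800 Hz
        seg = self._tone_segment(650.0)
        out = pitch_shift(seg, DEFAULT_PITCH_FACTOR)
        bin_hz = seg.fs / seg.samples.size
        assert abs(fft_peak_hz(out.samples, out.fs) - 800.0) <= bin_hz

    def test_label_and_duration_preserved(self):
        seg = self._tone_segment(200.0)
        out = pitch_shift(seg, 1.1)
        assert out.label == seg.label
        assert out.samples.size == seg.samples.size and out.fs == seg.fs

    def test_aliasing_guard(self):
        seg = self._tone_segment(100.0)
        with pytest.raises(ValidationError):
            pitch_shift(seg, 1.6, f_high=650.0)  # 650*1.6 >= 1000
        with pytest.raises(ValidationError):
            pitch_shift(seg, -1.0)


class TestBalanceClasses:
    def test_already_balanced_unchanged(self):
        ds = make_dataset(10, 10)
        out = balance_classes(ds, seed=0)
        assert len(out) == 20 and out.n_normal == out.n_abnormal == 10

    def test_minority_augmented_to_parity(self):
        ds = make_dataset(10, 6, seg_len=256)
        out = balance_classes(ds, seed=0)
        assert out.n_normal == out.n_abnormal == 10
        new = [s for s in out.segments if s.augmented]
        assert len(new) == 4
        assert all(s.label == "abnormal" for s in new)
        # originals all still present
        assert len(out) == len(ds) + 4

    def test_single_class_rejected(self):
        ds = make_dataset(1, 0)
        with pytest.raises(ValidationError):
            balance_classes(ds, seed=0)

    def test_deterministic_given_seed(self):
        ds = make_dataset(9, 4, seg_len=128)
        a = balance_classes(ds, seed=5)
        b = balance_classes(ds, seed=5)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.samples, sb.samples)


class TestDatasetInvariants:
    def test_mixed_lengths_rejected(self):
        s1 = Segment(samples=np.zeros(8), fs=10, label="normal")
        s2 = Segment(samples=np.zeros(9), fs=10, label="normal")
        with pytest.raises(ValidationError):
            LabeledDataset([s1, s2])

    def test_to_arrays_positive_class_is_abnormal(self):
        ds = make_dataset(2, 3)
        X, y = ds.to_arrays()
        assert X.shape == (5, 8)
        assert y.sum() == 3
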