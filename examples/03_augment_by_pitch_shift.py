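"""Pitch-shift augmentation: stretch spectral content, preserve duration.

The default factor 800/650 maps the 60-650 Hz heart-sound band onto
60-800 Hz.  Class balancing appends pitch-shifted copies of
minority-class windows until the counts match, never touching originals.
"""

import numpy as np

from pcgnet import (
    DEFAULT_PITCH_FACTOR,
    LabeledDataset,
    Segment,
    balance_classes,
    pitch_shift,
)
from pcgnet.signal_io import fft_peak_hz

fs = 2000.0
t = np.arange(int(4 * fs)) / fs
tone = Segment(samples=np.sin(2 * np.pi * 650.0 * t), fs=fs, label="abnormal")
shifted = pitch_shift(tone, DEFAULT_PITCH_FACTOR)
print(f"factor {DEFAULT_PITCH_FACTOR:.4f}: "
      f"{fft_peak_hz(tone.samples, fs):.2f} Hz -> {fft_peak_hz(shifted.samples, fs):.2f} Hz, "
      f"length {tone.samples.size} -> {shifted.samples.size} samples")

rng = np.random.default_rng(0)
segments = [Segment(samples=rng.standard_normal(8000), fs=fs, label="normal",
                    source_id=f"n{i}") for i in range(10)]
segments += [Segment(samples=rng.standard_normal(8000), fs=fs, label="abnormal",
                     source_id=f"a{i}") for i in range(6)]
balanced = balance_classes(LabeledDataset(segments), seed=1)
n_aug = sum(1 for s in balanced.segments if s.augmented)
print(f"10 normal / 6 abnormal -> {balanced.n_normal} / {balanced.n_abnormal} "
      f"({n_aug} augmented copies appended)")
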