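"""Fixed-length windowing, padding, and pitch-shift augmentation.

The network consumes windows of one exact length (4 s at 2000 Hz = 8000
samples by default), so every recording is tiled into such windows and a
trailing partial window is padded to full length.  Heart sounds are
near-periodic, so the default padding wraps the window's own content
cyclically instead of appending silence.

Pitch-shifting is the label-preserving augmentation: it rescales all
frequency content by a multiplicative factor while keeping the duration
fixed, which is how the minority class is topped up to balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import resample_poly

from .errors import ValidationError
from .signal_io import AudioSignal

#: Default pitch-shift ratio: stretches the 60–650 Hz heart-sound band
#: up to 60–800 Hz.
DEFAULT_PITCH_FACTOR = 800.0 / 650.0

DEFAULT_SEGMENT_SECONDS = 4.0
DEFAULT_OVERLAP = 0.0


@dataclass
class Segment:
    """A fixed-length labeled window of a recording; the unit of model input."""

    samples: np.ndarray
    fs: float
    label: str
    source_id: str = ""
    start_s: float = 0.0
    augmented: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("Segment.samples must be one-dimensional")
        if self.start_s < 0:
            raise ValidationError(f"start_s must be >= 0, got {self.start_s}")
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")

    def copy(self) -> "Segment":
        return replace(self, samples=self.samples.copy())


@dataclass
class LabeledDataset:
    """A collection of equal-length segments with per-class tallies."""

    segments: List[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.segments:
            lengths = {s.samples.size for s in self.segments}
            rates = {s.fs for s in self.segments}
            if len(lengths) > 1:
                raise ValidationError(f"segments have mixed lengths: {sorted(lengths)}")
            if len(rates) > 1:
                raise ValidationError(f"segments have mixed sampling rates: {sorted(rates)}")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def n_normal(self) -> int:
        return sum(1 for s in self.segments if s.label == "normal")

    @property
    def n_abnormal(self) -> int:
        return sum(1 for s in self.segments if s.label == "abnormal")

    def to_arrays(self, dtype=np.float32):
        """Stack into (X, y) with y = 1 for the positive class, abnormal."""
        X = np.stack([s.samples for s in self.segments]).astype(dtype)
        y = np.array([1 if s.label == "abnormal" else 0 for s in self.segments], dtype=np.int64)
        return X, y


def pad_segment(samples, target_len: int, mode: str = "wrap") -> np.ndarray:
    """Extend ``samples`` to ``target_len``.

    ``wrap`` repeats the input cyclically — appropriate for the periodic
    cardiac cycle; ``zero`` appends silence.
    """
    samples = np.asarray(samples, dtype=np.float64)
    n = samples.size
    if n == 0:
        raise ValidationError("cannot pad an empty segment")
    if n > target_len:
        raise ValidationError(f"input length {n} exceeds target {target_len}")
    if n == target_len:
        return samples.copy()
    if mode == "wrap":
        reps = math.ceil(target_len / n)
        return np.tile(samples, reps)[:target_len]
    if mode == "zero":
        return np.pad(samples, (0, target_len - n))
    raise ValidationError(f"unknown padding mode {mode!r} (expected 'wrap' or 'zero')")


def segment_signal(
    signal: AudioSignal,
    seg_seconds: float = DEFAULT_SEGMENT_SECONDS,
    overlap_frac: float = DEFAULT_OVERLAP,
    pad_mode: str = "wrap",
) -> List[Segment]:
    """Cut a recording into fixed-length windows.

    Windows hold exactly ``round(seg_seconds * fs)`` samples, spaced by a
    hop of ``seg_seconds * (1 - overlap_frac)``; a trailing partial
    window is padded to full length.  Every window inherits the
    recording's label and source_id.
    """
    if seg_seconds <= 0:
        raise ValidationError(f"seg_seconds must be positive, got {seg_seconds}")
    if not (0.0 <= overlap_frac < 1.0):
        raise ValidationError(f"overlap_frac must lie in [0, 1), got {overlap_frac}")
    if signal.label is None:
        raise ValidationError(f"cannot segment unlabeled signal {signal.source_id!r}")

    fs = signal.fs
    x = signal.samples
    seg_len = int(round(seg_seconds * fs))
    hop_len = max(1, int(round(seg_seconds * (1.0 - overlap_frac) * fs)))
    n_seg = max(1, math.ceil((x.size - seg_len) / hop_len) + 1)

    segments = []
    for j in range(n_seg):
        start = j * hop_len
        chunk = x[start : start + seg_len]
        if chunk.size < seg_len:
            chunk = pad_segment(chunk, seg_len, mode=pad_mode)
        segments.append(
            Segment(
                samples=chunk.copy(),
                fs=fs,
                label=signal.label,
                source_id=signal.source_id,
                start_s=start / fs,
            )
        )
    return segments


def pitch_shift(segment: Segment, factor: float, f_high: Optional[float] = None) -> Segment:
    """Move every narrowband component from f to f*factor; duration unchanged.

    Implemented as band-limited resampling by 1/factor followed by
    wrap-padding (factor > 1 shortens, so the tail is refilled cyclically)
    or trimming (factor < 1) back to the original length.

    ``f_high``, when given, is the highest frequency expected in the
    segment (e.g. the preprocessing passband edge); the call is rejected
    if ``f_high * factor`` would reach Nyquist and alias.
    """
    if factor <= 0:
        raise ValidationError(f"pitch factor must be positive, got {factor}")
    if f_high is not None and f_high * factor >= segment.fs / 2:
        raise ValidationError(
            f"pitch factor {factor:.4f} would move {f_high} Hz past Nyquist "
            f"({segment.fs / 2} Hz)"
        )
    n = segment.samples.size
    if factor == 1.0:
        out = segment.samples.copy()
    else:
        from fractions import Fraction

        frac = Fraction(1.0 / factor).limit_denominator(1000)
        resampled = resample_poly(segment.samples, frac.numerator, frac.denominator)
        if resampled.size >= n:
            out = resampled[:n]
        else:
            out = pad_segment(resampled, n, mode="wrap")
    return replace(segment, samples=out, augmented=True)


def balance_classes(
    dataset: LabeledDataset,
    policy: str = "augment_minority",
    pitch_factors: Sequence[float] = (DEFAULT_PITCH_FACTOR,),
    seed: int = 0,
) -> LabeledDataset:
    """Equalise class counts by pitch-shifting minority-class segments.

    Originals are never removed; new segments are flagged ``augmented``
    and keep the minority label.  Source segments are drawn in a seeded
    shuffled order (cycling if the imbalance exceeds the minority size)
    and each copy gets a factor drawn from ``pitch_factors``.
    """
    if policy != "augment_minority":
        raise ValidationError(f"unknown balancing policy {policy!r}")
    n_norm, n_abn = dataset.n_normal, dataset.n_abnormal
    if n_norm == 0 or n_abn == 0:
        raise ValidationError(
            f"balancing needs both classes present, got normal={n_norm} abnormal={n_abn}"
        )
    if not pitch_factors:
        raise ValidationError("pitch_factors must be non-empty")
    if n_norm == n_abn:
        return LabeledDataset(segments=list(dataset.segments))

    minority = "normal" if n_norm < n_abn else "abnormal"
    deficit = abs(n_norm - n_abn)
    pool = [s for s in dataset.segments if s.label == minority]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))

    new_segments = list(dataset.segments)
    for k in range(deficit):
        src = pool[order[k % len(pool)]]
        factor = float(pitch_factors[int(rng.integers(len(pitch_factors)))])
        new_segments.append(pitch_shift(src, factor))
    return LabeledDataset(segments=new_segments)
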