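"""Reading, writing and resampling heart-sound recordings.

Recordings arrive at whatever rate the stethoscope or archive used
(8 kHz locally captured, 44.1 kHz public archives); the pipeline works
at a canonical 2000 Hz, which keeps the full 20–650 Hz diagnostic band
below Nyquist while shrinking the model input to a tractable length
(8 s -> 16 000 samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import EmptySignalError, FormatError, ValidationError

#: Canonical sampling rate of the pipeline, Hz.
CANONICAL_FS = 2000

_PCM_SCALE = {
    np.dtype(np.int16): 2.0 ** 15,
    np.dtype(np.int32): 2.0 ** 31,
}


@dataclass
class AudioSignal:
    """A mono sampled waveform with its sampling rate and optional label.

    Amplitudes are dimensionless, nominally in [-1, 1].  ``label`` is
    ``"normal"``/``"abnormal"`` when known, else ``None``.
    """

    samples: np.ndarray
    fs: float
    source_id: str = ""
    label: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("AudioSignal.samples must be one-dimensional")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size < 1:
            raise ValidationError("AudioSignal must hold at least one sample")

    @property
    def duration_s(self) -> float:
        """Length of the recording in seconds (n_samples / fs, exact)."""
        return self.samples.size / self.fs

    def copy(self) -> "AudioSignal":
        return replace(self, samples=self.samples.copy(), meta=dict(self.meta))


def read_wav(path) -> AudioSignal:
    """Read a RIFF/WAVE file as a mono, [-1, 1]-scaled :class:`AudioSignal`.

    PCM16/PCM32, uint8 and IEEE-float dialects are accepted; multi-channel
    audio is averaged to mono (stethoscope audio is nominally mono, so a
    stereo file is a recording-chain artifact, not two sources).

    Raises
    ------
    FormatError
        If the file is not a readable WAV.
    EmptySignalError
        If the audio payload holds zero samples — a failure mode seen in
        field recordings; catch it to skip the file in a batch run.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        fs, data = wavfile.read(str(path))
    except EmptySignalError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise EmptySignalError(f"WAV file has no audio content: {path}")

    data = np.asarray(data)
    if data.dtype == np.uint8:  # unsigned 8-bit PCM is offset-binary
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:  # float32 / float64 already in [-1, 1]
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples=samples, fs=float(fs), source_id=path.stem)


def write_wav(signal: AudioSignal, path) -> None:
    """Write ``signal`` as a mono PCM16 WAV file.

    Samples are clipped to [-1, 1] before quantisation, so
    ``read_wav(write_wav(s))`` reproduces ``s`` within one PCM16 step
    (2**-15) for in-range input.
    """
    if not np.all(np.isfinite(signal.samples)):
        raise ValidationError("cannot write non-finite samples to WAV")
    fs = int(round(signal.fs))
    if fs <= 0 or abs(fs - signal.fs) > 1e-9:
        raise ValidationError(f"fs must be a positive integer for WAV output, got {signal.fs}")
    clipped = np.clip(signal.samples, -1.0, 1.0)
    # scale matches the read path (x/32768), so write-read stays within
    # one quantisation step; +1.0 saturates at 32767
    pcm = np.clip(np.round(clipped * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), fs, pcm)


def resample(signal: AudioSignal, target_fs: float) -> AudioSignal:
    """Band-limited (polyphase) resampling to ``target_fs`` Hz.

    The polyphase FIR includes the anti-alias filter the Nyquist
    criterion demands, so content below ``min(fs, target_fs)/2`` is
    preserved and nothing above it folds back.  Output length is
    ``round(n * target_fs / fs)``; duration is preserved to within one
    output sample.
    """
    if target_fs <= 0:
        raise ValidationError(f"target_fs must be positive, got {target_fs}")
    if abs(target_fs - signal.fs) < 1e-12:
        return signal.copy()

    # rational rate ratio; WAV headers carry integer rates, but guard anyway
    frac = _as_fraction(target_fs) / _as_fraction(signal.fs)
    up, down = frac.numerator, frac.denominator
    out = resample_poly(signal.samples, up, down)
    n_out = int(round(signal.samples.size * target_fs / signal.fs))
    out = out[:n_out] if out.size >= n_out else np.pad(out, (0, n_out - out.size))
    return replace(signal, samples=out, fs=float(target_fs), meta=dict(signal.meta))


def _as_fraction(x: float):
    from fractions import Fraction

    if abs(x - round(x)) < 1e-9:
        return Fraction(int(round(x)))
    return Fraction(x).limit_denominator(10_000)


def fft_peak_hz(samples: np.ndarray, fs: float) -> float:
    """Frequency (Hz) of the largest rFFT magnitude bin; DC excluded."""
    samples = np.asarray(samples, dtype=np.float64)
    spec = np.abs(np.fft.rfft(samples))
    spec[0] = 0.0
    freqs = np.fft.rfftfreq(samples.size, d=1.0 / fs)
    return float(freqs[int(np.argmax(spec))])


def _require_positive_duration(seconds: float, name: str) -> None:
    if not (seconds > 0 and math.isfinite(seconds)):
        raise ValidationError(f"{name} must be a positive finite duration, got {seconds}")
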