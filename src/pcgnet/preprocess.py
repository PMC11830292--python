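"""Band-pass filtering and amplitude normalisation of heart-sound signals.

Two passbands are in clinical use here and both ship as named presets:

* ``physio``  — 20–500 Hz, 4th-order Butterworth.  The default: it covers
  S1/S2 fundamentals plus murmur energy while rejecting sub-20 Hz rumble
  (handling noise, chest movement) and high-frequency friction artifacts.
* ``audacity`` — 60–650 Hz, order 8 (a 48 dB/octave roll-off is eight
  poles per edge), the setting used when cleaning recordings in an audio
  editor before resampling.

Filtering is applied zero-phase (forward–backward), so the sharp S1/S2
transients keep their timing; the price is that the realised attenuation
is the square of the designed magnitude response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .signal_io import AudioSignal


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design parameters: cutoffs in Hz and Butterworth order."""

    f_low: float
    f_high: float
    order: int = 4
    design: str = "butterworth"

    def validate(self, fs: float) -> None:
        if self.design != "butterworth":
            raise ValidationError(f"unsupported filter design: {self.design!r}")
        if self.order < 1:
            raise ValidationError(f"filter order must be >= 1, got {self.order}")
        if not (0 < self.f_low < self.f_high):
            raise ValidationError(
                f"need 0 < f_low < f_high, got ({self.f_low}, {self.f_high})"
            )
        if self.f_high >= fs / 2:
            raise ValidationError(
                f"f_high={self.f_high} Hz reaches Nyquist ({fs / 2} Hz at fs={fs}); "
                "resample first or lower the cutoff"
            )


#: Named passband presets (see module docstring).
PRESETS = {
    "physio": FilterSpec(20.0, 500.0, order=4),
    "audacity": FilterSpec(60.0, 650.0, order=8),
}

DEFAULT_PRESET = "physio"


def get_preset(name: str) -> FilterSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown filter preset {name!r}; known: {sorted(PRESETS)}"
        ) from None


def design_bandpass(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design a digital Butterworth band-pass; returns second-order sections.

    The magnitude response is maximally flat in the passband and crosses
    -3 dB at each cutoff (Butterworth definition).
    """
    spec.validate(fs)
    return sps.butter(
        spec.order, [spec.f_low, spec.f_high], btype="bandpass", fs=fs, output="sos"
    )


def frequency_response(sos: np.ndarray, fs: float, freqs) -> np.ndarray:
    """|H(f)| of a designed filter at the given frequencies (Hz)."""
    _, h = sps.sosfreqz(sos, worN=np.atleast_1d(np.asarray(freqs, float)), fs=fs)
    return np.abs(h)


def bandpass_filter(signal: AudioSignal, spec: FilterSpec) -> AudioSignal:
    """Zero-phase band-pass filtering; length, fs, label, source_id preserved."""
    sos = design_bandpass(spec, signal.fs)
    # sosfiltfilt needs enough samples for its edge padding
    min_len = 3 * (2 * spec.order) + 1
    if signal.samples.size <= min_len:
        raise ValidationError(
            f"signal of {signal.samples.size} samples too short for order-"
            f"{spec.order} zero-phase filtering (needs > {min_len})"
        )
    out = sps.sosfiltfilt(sos, signal.samples)
    return replace(signal, samples=np.asarray(out), meta=dict(signal.meta))


def normalize(signal: AudioSignal) -> AudioSignal:
    """Peak-normalise so max |sample| = 1; an all-zero signal passes through.

    Peak (not z-score) scaling keeps zero-padding exactly zero and
    preserves the waveform shape up to one positive scalar.
    """
    peak = float(np.max(np.abs(signal.samples)))
    if peak == 0.0:
        warnings.warn(
            f"normalize: signal {signal.source_id!r} is identically zero; returned unchanged",
            RuntimeWarning,
            stacklevel=2,
        )
        out = signal.copy()
        out.meta["normalize_degenerate"] = True
        return out
    return replace(signal, samples=signal.samples / peak, meta=dict(signal.meta))
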