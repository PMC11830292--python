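"""Spectrograms and band-energy summaries for QC.

Normal heart sounds concentrate their power in the S1/S2 fundamentals
below ~200 Hz; systolic murmurs add broadband energy around 250–350 Hz.
A short-time Fourier magnitude (Hanning window, 25 ms / 50 % overlap by
default — mid-range of standard auscultation practice) and a simple
periodogram band-power fraction are enough to see both effects and to
verify that pitch-shift augmentation moved energy where intended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .signal_io import AudioSignal

DEFAULT_WINDOW_MS = 25.0
DEFAULT_OVERLAP = 0.5


@dataclass
class Spectrogram:
    """STFT magnitude (frequency x time) with its axes and window settings."""

    magnitudes: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    window_ms: float
    overlap_frac: float


def spectrogram(
    signal: AudioSignal,
    window_ms: float = DEFAULT_WINDOW_MS,
    overlap_frac: float = DEFAULT_OVERLAP,
) -> Spectrogram:
    """One-sided STFT magnitude with a Hanning window."""
    if not (5.0 <= window_ms <= 200.0):
        raise ValidationError(f"window_ms must lie in [5, 200], got {window_ms}")
    if not (0.0 <= overlap_frac <= 0.95):
        raise ValidationError(f"overlap_frac must lie in [0, 0.95], got {overlap_frac}")
    nperseg = int(round(window_ms * signal.fs / 1000.0))
    if nperseg < 2:
        raise ValidationError(f"window of {window_ms} ms is under 2 samples at fs={signal.fs}")
    if nperseg > signal.samples.size:
        raise ValidationError(
            f"window ({nperseg} samples) longer than signal ({signal.samples.size})"
        )
    noverlap = int(round(overlap_frac * nperseg))
    freqs, times, mags = sps.spectrogram(
        signal.samples,
        fs=signal.fs,
        window=sps.get_window("hann", nperseg),
        nperseg=nperseg,
        noverlap=noverlap,
        mode="magnitude",
    )
    return Spectrogram(
        magnitudes=mags,
        freqs=freqs,
        times=times,
        window_ms=window_ms,
        overlap_frac=overlap_frac,
    )


def power_spectrum(samples: np.ndarray, fs: float):
    """One-sided periodogram scaled so the powers sum to mean(x**2)."""
    samples = np.asarray(samples, dtype=np.float64)
    freqs, pxx = sps.periodogram(
        samples, fs=fs, window="boxcar", scaling="spectrum", detrend=False
    )
    return freqs, pxx


def band_energy_fraction(signal: AudioSignal, f_lo: float, f_hi: float) -> float:
    """Fraction of total spectral power lying in [f_lo, f_hi]."""
    if not (0.0 <= f_lo < f_hi <= signal.fs / 2):
        raise ValidationError(
            f"band [{f_lo}, {f_hi}] invalid at fs={signal.fs} (need 0 <= lo < hi <= fs/2)"
        )
    freqs, pxx = power_spectrum(signal.samples, signal.fs)
    total = float(pxx.sum())
    if total == 0.0:
        return 0.0
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    return float(pxx[in_band].sum() / total)


def save_spectrogram_png(spec: Spectrogram, path, title: str = "") -> None:
    """Render a spectrogram to PNG (QC aid); requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    db = 20.0 * np.log10(np.maximum(spec.magnitudes, 1e-12))
    mesh = ax.pcolormesh(spec.times, spec.freqs, db, shading="auto", cmap="magma")
    fig.colorbar(mesh, ax=ax, label="magnitude (dB)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
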