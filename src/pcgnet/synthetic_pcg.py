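"""Synthetic phonocardiogram generator.

A normal heart cycle is modelled as two short Gaussian-windowed tone
bursts — S1 (valve closure at systole onset, 60–120 Hz) and S2 (semilunar
closure, 80–160 Hz, shorter and slightly higher) — repeating at a
pediatric heart rate (70–140 bpm), over a white-noise floor.  An
abnormal recording adds a systolic murmur: band-limited noise in the
250–350 Hz band gated over the S1→S2 interval, at a configurable
signal-to-murmur ratio (default 6 dB: clearly learnable, not trivially
separable).  Onset and amplitude jitter (±5 %) keep recordings from
being metronomic.

Everything is a deterministic function of the seed; per-recording seeds
are spawned from the master seed so any single file can be regenerated
in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ValidationError
from .signal_io import AudioSignal, write_wav

LABELS = ("normal", "abnormal")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults give 10-s pediatric recordings at 2 kHz."""

    fs: float = 2000.0
    duration_s: float = 10.0
    heart_rate_bpm: Tuple[float, float] = (70.0, 140.0)
    s1_freq: Tuple[float, float] = (60.0, 120.0)
    s2_freq: Tuple[float, float] = (80.0, 160.0)
    murmur_band: Tuple[float, float] = (250.0, 350.0)
    murmur_snr_db: float = 6.0
    noise_floor_db: float = -30.0
    jitter_frac: float = 0.05
    systole_frac: float = 0.35  # S2 onset as a fraction of the cycle
    seed: int = 0

    def validate(self) -> None:
        nyq = self.fs / 2
        for name in ("s1_freq", "s2_freq", "murmur_band"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi < nyq):
                raise ValidationError(f"{name}=({lo}, {hi}) must satisfy 0 < lo < hi < {nyq}")
        hr_lo, hr_hi = self.heart_rate_bpm
        if not (0 < hr_lo <= hr_hi):
            raise ValidationError(f"heart_rate_bpm range invalid: {self.heart_rate_bpm}")
        if self.duration_s <= 2 * (60.0 / hr_lo):
            raise ValidationError(
                f"duration_s={self.duration_s} too short for at least two cycles "
                f"at {hr_lo} bpm"
            )
        if not (0 <= self.jitter_frac < 0.5):
            raise ValidationError(f"jitter_frac must lie in [0, 0.5), got {self.jitter_frac}")


def _tone_burst(t: np.ndarray, onset: float, dur: float, freq: float, amp: float) -> np.ndarray:
    """Gaussian-windowed tone centred dur/2 after onset."""
    centre = onset + dur / 2.0
    sigma = dur / 6.0
    env = np.exp(-0.5 * ((t - centre) / sigma) ** 2)
    env[np.abs(t - centre) > dur] = 0.0
    return amp * env * np.sin(2 * math.pi * freq * (t - onset))


def generate_pcg(
    label: str,
    config: SynthConfig = SynthConfig(),
    seed: Optional[int] = None,
    source_id: str = "",
) -> AudioSignal:
    """One labeled synthetic recording, fully determined by the seed."""
    if label not in LABELS:
        raise ValidationError(f"label must be one of {LABELS}, got {label!r}")
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)

    heart_rate = rng.uniform(*config.heart_rate_bpm)
    period = 60.0 / heart_rate
    n_cycles = math.floor(config.duration_s / period)
    s1_f = rng.uniform(*config.s1_freq)
    s2_f = rng.uniform(*config.s2_freq)
    s1_dur, s2_dur = 0.10, 0.08

    # non-accumulating onset jitter keeps the cycle count exact
    murmur_gate = np.zeros(n)
    for i in range(n_cycles):
        onset = i * period + (rng.uniform(-1, 1) * config.jitter_frac * period if i else 0.0)
        onset = max(onset, 0.0)
        a1 = 1.0 * (1 + rng.uniform(-1, 1) * config.jitter_frac)
        a2 = 0.7 * (1 + rng.uniform(-1, 1) * config.jitter_frac)
        x += _tone_burst(t, onset, s1_dur, s1_f, a1)
        x += _tone_burst(t, onset + config.systole_frac * period, s2_dur, s2_f, a2)
        # systole: from end of S1 to onset of S2
        lo = int(round((onset + s1_dur) * fs))
        hi = int(round((onset + config.systole_frac * period) * fs))
        murmur_gate[max(lo, 0) : max(hi, 0)] = 1.0

    heart_rms = float(np.sqrt(np.mean(x**2)))

    if label == "abnormal":
        raw = rng.standard_normal(n)
        sos = sps.butter(4, list(config.murmur_band), btype="bandpass", fs=fs, output="sos")
        murmur = sps.sosfiltfilt(sos, raw) * murmur_gate
        m_rms = float(np.sqrt(np.mean(murmur**2)))
        if m_rms > 0:
            # murmur level relative to the whole-record S1/S2 RMS: higher
            # SNR = louder murmur; at -inf dB the classes coincide
            target = heart_rms * 10.0 ** (config.murmur_snr_db / 20.0)
            x = x + murmur * (target / m_rms)

    noise = rng.standard_normal(n)
    x = x + noise * heart_rms * 10.0 ** (config.noise_floor_db / 20.0)

    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak  # headroom for PCM16 output
    return AudioSignal(
        samples=x,
        fs=fs,
        source_id=source_id,
        label=label,
        meta={"n_cycles": n_cycles, "heart_rate_bpm": heart_rate},
    )


def derive_seed(master_seed: int, index: int) -> int:
    """Stable per-recording seed below 2**31, spawned from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def generate_signals(
    n_normal: int,
    n_abnormal: int,
    config: SynthConfig = SynthConfig(),
) -> List[AudioSignal]:
    """In-memory dataset: n_normal + n_abnormal recordings, seeded per file."""
    if n_normal < 0 or n_abnormal < 0:
        raise ValidationError("counts must be >= 0")
    labels = ["normal"] * n_normal + ["abnormal"] * n_abnormal
    return [
        generate_pcg(
            lab,
            config,
            seed=derive_seed(config.seed, i),
            source_id=f"synth_{i:05d}_{lab}",
        )
        for i, lab in enumerate(labels)
    ]


def generate_dataset(
    n_normal: int,
    n_abnormal: int,
    config: SynthConfig,
    out_dir,
) -> Path:
    """Write WAV files plus a ``path,label`` CSV manifest; returns its path.

    File *i* is generated from ``derive_seed(config.seed, i)``, so any
    single recording is regenerable in isolation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sig in generate_signals(n_normal, n_abnormal, config):
        wav_path = out_dir / f"{sig.source_id}.wav"
        write_wav(sig, wav_path)
        rows.append({"path": str(wav_path), "label": sig.label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["path", "label"]).to_csv(manifest, index=False)
    return manifest
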