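import numpy as np
import pytest

from pcgnet.segment_augment import LabeledDataset, Segment
from pcgnet.signal_io import AudioSignal


def make_sine(freq_hz: float, fs: float = 2000.0, seconds: float = 1.0, amp: float = 1.0,
              label=None, source_id: str = "tone") -> AudioSignal:
    t = np.arange(int(round(seconds * fs))) / fs
    return AudioSignal(samples=amp * np.sin(2 * np.pi * freq_hz * t), fs=fs,
                       source_id=source_id, label=label)


def make_dataset(n_normal: int, n_abnormal: int, seg_len: int = 8,
                 segs_per_source: int = 1, fs: float = 2000.0) -> LabeledDataset:
    """Tiny synthetic segment collection for bookkeeping tests."""
    rng = np.random.default_rng(42)
    segments = []
    idx = 0
    for label, count in (("normal", n_normal), ("abnormal", n_abnormal)):
        n_sources, rem = divmod(count, segs_per_source)
        sizes = [segs_per_source] * n_sources + ([rem] if rem else [])
        for size in sizes:
            sid = f"{label}_{idx:06d}"
            idx += 1
            for j in range(size):
                segments.append(Segment(samples=rng.standard_normal(seg_len), fs=fs,
                                        label=label, source_id=sid, start_s=float(j)))
    return LabeledDataset(segments)


@pytest.fixture
def sine_250hz():
    return make_sine(250.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
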