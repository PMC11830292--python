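"""Band-pass filter, resample and window a recording into model inputs.

The canonical chain: 20-500 Hz 4th-order Butterworth (zero-phase) at the
native rate, resampling to 2000 Hz, peak normalisation, then disjoint
4-s windows of exactly 8000 samples; a trailing partial window is
wrap-padded using the heart cycle's periodicity.
"""

from pcgnet import (
    FilterSpec,
    PipelineConfig,
    SynthConfig,
    design_bandpass,
    frequency_response,
    generate_pcg,
    preprocess_signal,
    segment_signal,
)

# the designed filter hits -3 dB at its cutoffs and unity in the passband
fs = 2000.0
sos = design_bandpass(FilterSpec(20.0, 500.0, order=4), fs)
for f in (20.0, 100.0, 500.0):
    print(f"|H({f:5.0f} Hz)| = {frequency_response(sos, fs, [f])[0]:.3f}")

# a 10-s recording tiles into three 4-s windows (the third wrap-padded)
raw = generate_pcg("abnormal", SynthConfig(duration_s=10.0, fs=2000.0), seed=5)
clean = preprocess_signal(raw, PipelineConfig())
segments = segment_signal(clean, seg_seconds=4.0, overlap_frac=0.0)
print(f"\n{raw.duration_s:.0f}-s recording -> {len(segments)} windows "
      f"of {segments[0].samples.size} samples")
for seg in segments:
    print(f"  window at {seg.start_s:4.1f} s, label {seg.label}")
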