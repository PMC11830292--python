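"""End-to-end orchestration: simulate/load -> preprocess -> segment ->
augment -> split -> train -> evaluate.

The CLI, the example scripts and the desk-scale experiments all drive
this module; nothing here is more than glue over the stage modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import preprocess, segment_augment, signal_io
from .cnn_model import ModelConfig, TrainedModel, build_model
from .dataset_split import SplitResult, read_manifest, split_dataset
from .errors import EmptySignalError, FormatError, ValidationError
from .segment_augment import LabeledDataset
from .signal_io import CANONICAL_FS, AudioSignal
from .synthetic_pcg import SynthConfig
from .train_eval import TrainConfig, evaluate, train

log = logging.getLogger("pcgnet")


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the pipeline in one (flat) place.

    Defaults reproduce the canonical workflow: resample to 2000 Hz,
    20–500 Hz 4th-order Butterworth, peak normalisation, disjoint 4-s
    windows with wrap padding, minority-class pitch-shift balancing on
    the training partition only, sequential 15/15 split grouped by
    recording.
    """

    target_fs: float = float(CANONICAL_FS)
    filter_preset: str = preprocess.DEFAULT_PRESET
    filter_f_low: Optional[float] = None  # override preset when set
    filter_f_high: Optional[float] = None
    filter_order: Optional[int] = None
    segment_seconds: float = segment_augment.DEFAULT_SEGMENT_SECONDS
    segment_overlap: float = segment_augment.DEFAULT_OVERLAP
    pad_mode: str = "wrap"
    augment: bool = True
    pitch_factors: Tuple[float, ...] = (segment_augment.DEFAULT_PITCH_FACTOR,)
    test_frac: float = 0.15
    val_frac: float = 0.15
    split_mode: str = "sequential"
    seed: int = 0

    def filter_spec(self) -> preprocess.FilterSpec:
        spec = preprocess.get_preset(self.filter_preset)
        if self.filter_f_low is not None or self.filter_f_high is not None or self.filter_order is not None:
            spec = preprocess.FilterSpec(
                f_low=self.filter_f_low if self.filter_f_low is not None else spec.f_low,
                f_high=self.filter_f_high if self.filter_f_high is not None else spec.f_high,
                order=self.filter_order if self.filter_order is not None else spec.order,
            )
        return spec

    @property
    def segment_len(self) -> int:
        return int(round(self.segment_seconds * self.target_fs))


def config_from_mapping(mapping: dict) -> PipelineConfig:
    """Build a PipelineConfig from a flat key/value mapping.

    Unknown keys are rejected by name, so a typo in a config file fails
    loudly instead of silently running with defaults.
    """
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}")
    kwargs = dict(mapping)
    if "pitch_factors" in kwargs:
        kwargs["pitch_factors"] = tuple(float(v) for v in kwargs["pitch_factors"])
    return PipelineConfig(**kwargs)


def load_config_file(path) -> PipelineConfig:
    """Read a ``key = value`` / ``key: value`` text config file."""
    mapping = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        sep = "=" if "=" in line else (":" if ":" in line else None)
        if sep is None:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split(sep, 1))
        mapping[key] = _coerce(value)
    return config_from_mapping(mapping)


def _coerce(value: str):
    if "," in value:
        return tuple(_coerce(v.strip()) for v in value.split(","))
    low = value.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", "null", ""):
        return None
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


# ---------------------------------------------------------------------------
# stages


def preprocess_signal(signal: AudioSignal, cfg: PipelineConfig) -> AudioSignal:
    """Filter at the native rate, resample to canonical, peak-normalise."""
    spec = cfg.filter_spec()
    out = preprocess.bandpass_filter(signal, spec)
    out = signal_io.resample(out, cfg.target_fs)
    return preprocess.normalize(out)


def signals_to_dataset(
    signals: Sequence[AudioSignal], cfg: PipelineConfig
) -> LabeledDataset:
    """Preprocess and window a batch of labeled recordings."""
    segments = []
    for sig in signals:
        clean = preprocess_signal(sig, cfg)
        segments.extend(
            segment_augment.segment_signal(
                clean, cfg.segment_seconds, cfg.segment_overlap, pad_mode=cfg.pad_mode
            )
        )
    return LabeledDataset(segments)


def load_manifest_signals(manifest_path, skip_log: Optional[list] = None) -> List[AudioSignal]:
    """Read every WAV in a manifest, skipping (and logging) unreadable or
    empty files — the batch-robustness behaviour field recordings need."""
    df = read_manifest(manifest_path)
    signals = []
    for _, row in df.iterrows():
        try:
            sig = signal_io.read_wav(row["path"])
        except (FormatError, EmptySignalError) as exc:
            log.warning("skipping %s: %s", row["path"], exc)
            if skip_log is not None:
                skip_log.append({"path": row["path"], "reason": str(exc)})
            continue
        sig.label = row["label"]
        signals.append(sig)
    return signals


def split_and_balance(
    dataset: LabeledDataset, cfg: PipelineConfig
) -> SplitResult:
    """Split first, then balance only the training partition (no leakage)."""
    split = split_dataset(
        dataset,
        test_frac=cfg.test_frac,
        val_frac=cfg.val_frac,
        seed=cfg.seed,
        mode=cfg.split_mode,
    )
    if cfg.augment:
        balanced = segment_augment.balance_classes(
            split.train, pitch_factors=cfg.pitch_factors, seed=cfg.seed
        )
        split = replace(split, train=balanced)
    return split


@dataclass
class ExperimentResult:
    model: TrainedModel
    split: SplitResult
    val_report: dict
    test_report: dict
    history: List[dict] = field(default_factory=list)


def run_experiment(
    signals: Sequence[AudioSignal],
    cfg: PipelineConfig = PipelineConfig(),
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
) -> ExperimentResult:
    """The full workflow on in-memory recordings; returns model + reports."""
    dataset = signals_to_dataset(signals, cfg)
    split = split_and_balance(dataset, cfg)
    if model_config is None:
        model_config = ModelConfig(input_len=cfg.segment_len, seed=cfg.seed)
    if train_config is None:
        train_config = TrainConfig(seed=cfg.seed)
    model = build_model(model_config)
    log.info(
        "training on %d segments (val %d, test %d), seed %d",
        len(split.train), len(split.val), len(split.test), cfg.seed,
    )
    model = train(model, split.train, split.val, train_config)
    val_report = evaluate(model, split.val)
    test_report = evaluate(model, split.test)
    return ExperimentResult(
        model=model,
        split=split,
        val_report=val_report,
        test_report=test_report,
        history=model.training_history,
    )
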