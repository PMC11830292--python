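"""Train/validation/test partitioning of segment datasets.

Sizing is *sequential*: the test share is rounded off the whole first,
then the validation share off the remainder, and training takes the
rest.  With 15 %/15 % on 15,231 segments this yields 11,004 / 1,942 /
2,285 — whereas naive simultaneous 70/15/15 rounding gives a different
test size — so sequential is the default and a ``simultaneous`` mode is
available for comparison.

Splitting is stratified by class and grouped by ``source_id``: all
segments cut from one recording travel together, so a recording never
leaks across the train/test boundary.  When every segment has a distinct
source, the sequential sizes are hit exactly; with multi-segment
recordings the greedy group assignment lands as close as group sizes
allow.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .segment_augment import LabeledDataset, Segment

VALID_LABELS = ("normal", "abnormal")


@dataclass
class SplitResult:
    """A disjoint train/val/test partition and the seed that produced it."""

    train: LabeledDataset
    val: LabeledDataset
    test: LabeledDataset
    seed: int

    def sizes(self) -> Tuple[int, int, int]:
        return len(self.train), len(self.val), len(self.test)


def class_counts(dataset: LabeledDataset) -> Tuple[int, int]:
    """(n_normal, n_abnormal); always sums to len(dataset)."""
    n_normal = dataset.n_normal
    n_abnormal = dataset.n_abnormal
    other = len(dataset) - n_normal - n_abnormal
    if other:
        raise ValidationError(f"{other} segments carry labels outside {VALID_LABELS}")
    return n_normal, n_abnormal


def split_sizes(n: int, test_frac: float, val_frac: float, mode: str = "sequential"):
    """Partition sizes (n_train, n_val, n_test) for a dataset of ``n``.

    ``sequential`` (default): n_test = round(test_frac * n), then
    n_val = round(val_frac * (n - n_test)); rounding is round-half-even.
    ``simultaneous``: both rounded against n directly.
    """
    if not (0 <= test_frac < 1 and 0 <= val_frac < 1 and test_frac + val_frac < 1):
        raise ValidationError(
            f"fractions must satisfy test+val < 1, got ({test_frac}, {val_frac})"
        )
    if mode == "sequential":
        n_test = round(test_frac * n)
        n_val = round(val_frac * (n - n_test))
    elif mode == "simultaneous":
        n_test = round(test_frac * n)
        n_val = round(val_frac * n)
    else:
        raise ValidationError(f"unknown split mode {mode!r}")
    n_train = n - n_test - n_val
    if n_train < 0:
        raise ValidationError("fractions leave no training data")
    return n_train, n_val, n_test


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` across weights."""
    if total == 0 or weights.sum() == 0:
        return np.zeros_like(weights, dtype=int)
    quotas = total * weights / weights.sum()
    base = np.floor(quotas).astype(int)
    remainder = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:remainder]] += 1
    return base


def split_dataset(
    dataset: LabeledDataset,
    test_frac: float = 0.15,
    val_frac: float = 0.15,
    seed: int = 0,
    mode: str = "sequential",
) -> SplitResult:
    """Stratified, recording-grouped train/val/test split.

    Per class, recordings (source_id groups) are shuffled by ``seed`` and
    assigned greedily to the test then validation partitions until each
    class's apportioned share of the sequential sizes is met as closely
    as whole groups allow; the remainder trains.
    """
    n = len(dataset)
    if n < 3:
        raise ValidationError(f"need at least 3 segments to split, got {n}")
    class_counts(dataset)  # validates labels
    n_train, n_val, n_test = split_sizes(n, test_frac, val_frac, mode=mode)

    # per-class share of each partition (largest remainder keeps sums exact)
    labels = sorted({s.label for s in dataset.segments})
    per_class = np.array([sum(1 for s in dataset if s.label == lab) for lab in labels])
    test_targets = _apportion(n_test, per_class)
    val_targets = _apportion(n_val, per_class.copy() - test_targets)

    rng = np.random.default_rng(seed)
    parts: Dict[str, List[Segment]] = {"train": [], "val": [], "test": []}
    for lab, t_target, v_target in zip(labels, test_targets, val_targets):
        groups: Dict[str, List[Segment]] = defaultdict(list)
        for s in dataset.segments:
            if s.label == lab:
                # identity-keyed fallback keeps duplicates of an empty id apart
                groups[s.source_id or f"@{id(s)}"].append(s)
        keys = sorted(groups)
        rng.shuffle(keys)
        assigned_test = assigned_val = 0
        for key in keys:
            g = groups[key]
            if assigned_test < t_target and abs(assigned_test + len(g) - t_target) <= abs(
                assigned_test - t_target
            ):
                parts["test"].extend(g)
                assigned_test += len(g)
            elif assigned_val < v_target and abs(assigned_val + len(g) - v_target) <= abs(
                assigned_val - v_target
            ):
                parts["val"].extend(g)
                assigned_val += len(g)
            else:
                parts["train"].extend(g)

    return SplitResult(
        train=LabeledDataset(parts["train"]),
        val=LabeledDataset(parts["val"]),
        test=LabeledDataset(parts["test"]),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# manifest I/O


def read_manifest(path) -> pd.DataFrame:
    """Read a ``path,label`` CSV manifest; labels must be normal/abnormal."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise ValidationError(f"manifest {path} lacks columns: {sorted(missing)}")
    bad = set(df["label"].unique()) - set(VALID_LABELS)
    if bad:
        raise ValidationError(f"manifest {path} has unknown labels: {sorted(bad)}")
    return df


def write_split_manifest(split: SplitResult, path) -> None:
    """Write the partition as a CSV with source_id, label, start_s, split."""
    rows = []
    for name, part in (("train", split.train), ("val", split.val), ("test", split.test)):
        for s in part.segments:
            rows.append(
                {"source_id": s.source_id, "label": s.label, "start_s": s.start_s, "split": name}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
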