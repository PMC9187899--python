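"""Data conditioning: complete-case exclusion, shifted min-max
normalization, the 7:3 train/test split, and minority up-sampling.

The normalizer is deliberately not the textbook min-max: it maps

    x* = (x - 0.99 * min) / (max - min)

so a feature's training minimum lands slightly above zero instead of at
zero (x*(min) = 0.01 * min / (max - min)).  Values outside the training
range are left outside [0, 1]; nothing is clipped.  min/max are learned on
the training split only and reused for test/validation data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURES_35


class DegenerateFeatureError(ValueError):
    """A feature is constant on the training data (max == min)."""


@dataclass
class NormalizationParams:
    """Per-feature (min, max) learned from training data."""

    minmax: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.minmax.items():
            if hi < lo:
                raise ValueError(f"{name}: max < min ({hi} < {lo})")

    def to_json(self, path: str | Path) -> None:
        payload = {k: {"min": lo, "max": hi} for k, (lo, hi) in self.minmax.items()}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        payload = json.loads(Path(path).read_text())
        return cls({k: (v["min"], v["max"]) for k, v in payload.items()})


@dataclass
class SplitResult:
    train: pd.DataFrame
    test: pd.DataFrame
    seed: int
    ratio: float


@dataclass
class UpsampleConfig:
    """How synthetic minority records are produced.

    ``weights`` are the probabilities of the three mechanisms
    (replicate, median_synth, noise_jitter); ``noise_scale`` is the jitter
    standard deviation as a fraction of the per-feature minority IQR;
    ``target_ratio`` is the desired minority:majority ratio.
    """

    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    noise_scale: float = 0.1
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mechanism weights must be >= 0 and sum to 1")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be > 0")


def exclude_incomplete(
    table: pd.DataFrame, features: tuple[str, ...] = FEATURES_35
) -> tuple[pd.DataFrame, int]:
    """Drop every record with any missing blood-test value.

    Returns the complete-case table (original order preserved) and the
    number of excluded records.
    """
    complete = table[list(features)].notna().all(axis=1)
    kept = table.loc[complete].reset_index(drop=True)
    return kept, int((~complete).sum())


def fit_normalizer(
    train: pd.DataFrame, features: tuple[str, ...] = FEATURES_35
) -> NormalizationParams:
    """Learn per-feature (min, max) from the training table."""
    if len(train) == 0:
        raise ValueError("empty training table")
    minmax: dict[str, tuple[float, float]] = {}
    for name in features:
        col = train[name].to_numpy(dtype=float)
        lo, hi = float(np.min(col)), float(np.max(col))
        if hi == lo:
            raise DegenerateFeatureError(
                f"feature {name!r} is constant on the training data (value {lo})"
            )
        minmax[name] = (lo, hi)
    return NormalizationParams(minmax)


def apply_normalizer(params: NormalizationParams, table: pd.DataFrame) -> pd.DataFrame:
    """Apply x* = (x - 0.99*min) / (max - min) per feature.

    Out-of-training-range values map outside [0, 1] and are not clipped.
    """
    missing = [k for k in params.minmax if k not in table.columns]
    if missing:
        raise KeyError(f"table lacks normalizer features: {missing}")
    out = table.copy()
    for name, (lo, hi) in params.minmax.items():
        out[name] = (table[name].to_numpy(dtype=float) - 0.99 * lo) / (hi - lo)
    return out


def invert_normalizer(params: NormalizationParams, table: pd.DataFrame) -> pd.DataFrame:
    """Exact inverse of :func:`apply_normalizer`."""
    out = table.copy()
    for name, (lo, hi) in params.minmax.items():
        out[name] = table[name].to_numpy(dtype=float) * (hi - lo) + 0.99 * lo
    return out


def split_cohort(
    table: pd.DataFrame,
    ratio: float = 0.7,
    seed: int = 0,
    stratify_by: str | None = None,
) -> SplitResult:
    """Uniformly random 7:3 (by default) train/test partition.

    Train size is ``round(ratio * n)`` (round-half-even).  Optional
    stratification by a label column keeps the per-stratum ratio.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        perm = rng.permutation(n)
        n_train = round(ratio * n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
    else:
        train_parts = []
        for _, grp in table.groupby(stratify_by, sort=True):
            idx = grp.index.to_numpy()
            perm = rng.permutation(len(idx))
            k = round(ratio * len(idx))
            train_parts.append(idx[perm[:k]])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.setdiff1d(np.arange(n), train_idx)
    return SplitResult(
        train=table.iloc[train_idx].reset_index(drop=True),
        test=table.iloc[test_idx].reset_index(drop=True),
        seed=seed,
        ratio=ratio,
    )


def upsample_minority(
    train: pd.DataFrame,
    config: UpsampleConfig | None = None,
    label_col: str = "survived_28d",
    minority_label: int | None = None,
    features: tuple[str, ...] = FEATURES_35,
) -> pd.DataFrame:
    """Augment the minority class to (near) parity with the majority.

    Each synthetic record is produced by one of three mechanisms, chosen
    at random with the configured weights:

    * replicate — a verbatim copy of a random minority record;
    * median_synth — the per-feature minority medians, jittered;
    * noise_jitter — a random minority record plus noise of scale
      ``noise_scale * IQR`` per feature.

    Majority records are never touched; labels are never changed; the
    added rows carry ``synthetic = 1``.
    """
    if config is None:
        config = UpsampleConfig()
    labels = train[label_col]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("up-sampling needs both classes present")
    if minority_label is None:
        minority_label = counts.idxmin()
    n_min = int(counts[minority_label])
    n_maj = int(counts.drop(index=minority_label).max())
    out = train.copy()
    if "synthetic" not in out.columns:
        out["synthetic"] = 0
    n_new = int(round(config.target_ratio * n_maj)) - n_min
    if n_new <= 0:
        return out

    rng = np.random.default_rng(config.seed)
    minority = train.loc[labels == minority_label]
    feats = list(features)
    block = minority[feats].to_numpy(dtype=float)
    med = np.median(block, axis=0)
    iqr = np.quantile(block, 0.75, axis=0) - np.quantile(block, 0.25, axis=0)
    noise_sd = config.noise_scale * np.where(iqr > 0, iqr, 1e-12)

    mech = rng.choice(3, size=n_new, p=np.asarray(config.weights, dtype=float))
    pick = rng.integers(0, len(minority), size=n_new)
    new = minority.iloc[pick].reset_index(drop=True).copy()
    vals = new[feats].to_numpy(dtype=float)
    is_median = mech == 1
    vals[is_median] = med
    jitter_rows = mech != 0
    noise = rng.standard_normal((n_new, len(feats))) * noise_sd
    vals[jitter_rows] += noise[jitter_rows]
    new[feats] = vals
    new["synthetic"] = 1
    return pd.concat([out, new], ignore_index=True)
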