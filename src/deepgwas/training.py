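"""Labels, class rebalancing, and standardization for model training.

The label study (the larger, better-powered GWAS of the same trait)
defines Y = 1 iff its p-value is strictly below genome-wide significance
(5e-8 by default). Because significant variants are a tiny minority,
training uses under-sampling of label-0 variants at a configurable
negatives-per-positive ratio. Standardization parameters are fit on the
(under-sampled) training subset only and applied unchanged everywhere
else, so no test-set statistics ever leak into training.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GWS_ALPHA = 5e-8
UNDERSAMPLE_RATIO_DEFAULT = 10.0


@dataclass
class Scaler:
    """Per-feature z-scoring parameters fit on a training subset.

    Constant columns (sd == 0) are passed through unscaled and flagged.
    """

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # boolean mask of constant (untouched) columns

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "Scaler":
        if len(X) == 0:
            raise ValueError("cannot fit a scaler on an empty training set")
        arr = X.to_numpy(dtype=float)
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=0)
        constant = sd == 0
        if constant.any():
            logger.warning(
                "standardize: %d constant feature(s) passed through unscaled: %s",
                constant.sum(),
                [n for n, c in zip(X.columns, constant) if c],
            )
        return cls(list(X.columns), mean, sd, constant)

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            raise ValueError(
                f"feature schema mismatch: {list(X.columns)} vs {self.feature_names}"
            )
        return X.to_numpy(dtype=float)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        arr = self._check(X)
        sd = np.where(self.constant, 1.0, self.sd)
        mean = np.where(self.constant, 0.0, self.mean)
        return pd.DataFrame((arr - mean) / sd, index=X.index, columns=X.columns)

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        arr = self._check(X)
        sd = np.where(self.constant, 1.0, self.sd)
        mean = np.where(self.constant, 0.0, self.mean)
        return pd.DataFrame(arr * sd + mean, index=X.index, columns=X.columns)


@dataclass
class LabeledSet:
    """Feature matrix plus binary labels and input-study significance flags."""

    X: pd.DataFrame
    y: np.ndarray
    input_significant: np.ndarray
    scaler: Scaler | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y).astype(int)
        self.input_significant = np.asarray(self.input_significant).astype(bool)
        if len(self.X) != len(self.y) or len(self.y) != len(self.input_significant):
            raise ValueError("X, y, and input_significant lengths differ")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary")

    def subset(self, idx: np.ndarray) -> "LabeledSet":
        return LabeledSet(
            self.X.iloc[idx], self.y[idx], self.input_significant[idx], self.scaler
        )


def label_variants(
    label_stats: pd.DataFrame, alpha: float = GWS_ALPHA
) -> pd.Series:
    """Binary labels keyed by variant: 1 iff label-study p < alpha (strict)."""
    y = (label_stats["p_value"].to_numpy(dtype=float) < alpha).astype(int)
    return pd.Series(y, index=label_stats["key"].to_numpy())


def align_labels(feature_keys: pd.Index | np.ndarray, labels: pd.Series):
    """Join labels onto the feature-study variants; absentees are dropped.

    Returns (kept positional indices, aligned label array, n_dropped).
    """
    keys = pd.Index(feature_keys)
    aligned = labels.reindex(keys)
    keep = ~aligned.isna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("align_labels: %d variants absent from the label study dropped",
                       n_dropped)
    return np.flatnonzero(keep.to_numpy()), aligned[keep].to_numpy(dtype=int), n_dropped


def undersample_mask(
    y: np.ndarray, ratio: float = UNDERSAMPLE_RATIO_DEFAULT, seed: int = 0
) -> np.ndarray:
    """Positional indices of the under-sampled training subset (sorted).

    All positives are retained; ceil(ratio × #positives) negatives are
    drawn uniformly without replacement (all of them if fewer exist).
    Deterministic given the seed.
    """
    y = np.asarray(y).astype(int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0:
        raise ValueError("under-sampling requires at least one positive label; "
                         "the model is untrainable without positives")
    n_neg = min(len(neg), math.ceil(ratio * len(pos)))
    rng = np.random.default_rng(seed)
    sampled = rng.choice(neg, size=n_neg, replace=False) if n_neg else np.empty(0, int)
    return np.sort(np.concatenate([pos, sampled]))


def undersample(
    labeled: LabeledSet, ratio: float = UNDERSAMPLE_RATIO_DEFAULT, seed: int = 0
) -> tuple[LabeledSet, np.ndarray]:
    """Under-sampled subset of a labeled set; returns (subset, sampling mask)."""
    mask = undersample_mask(labeled.y, ratio=ratio, seed=seed)
    return labeled.subset(mask), mask


def standardize(
    train: LabeledSet, others: list[pd.DataFrame] | None = None
) -> tuple[LabeledSet, list[pd.DataFrame], Scaler]:
    """Fit z-scoring on the training subset; apply unchanged to other sets."""
    scaler = Scaler.fit(train.X)
    train_std = LabeledSet(
        scaler.transform(train.X), train.y, train.input_significant, scaler
    )
    others_std = [scaler.transform(X) for X in (others or [])]
    return train_std, others_std, scaler


def stratified_split(
    y: np.ndarray, val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic label-stratified train/validation index split."""
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(np.asarray(y) == cls)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * len(idx)))
        if len(idx) > 1:
            n_val = min(max(n_val, 1), len(idx) - 1)
        else:
            n_val = 0
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))
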