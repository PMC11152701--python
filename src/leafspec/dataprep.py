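"""Outlier screening and dataset splitting.

A single-task PLS1 model is fitted per pigment on all samples; samples whose
absolute residual exceeds a per-pigment threshold on ANY of the four
attributes are removed from ALL four (the multi-task union rule), so every
model family sees the same retained set. The retained samples are then split
3:1:1 into training/validation/testing under an explicit seed, and the same
split is reused for single- and multi-task models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .containers import PIGMENTS, ParameterError

MAX_SCREEN_COMPONENTS = 15


def _as_2d_targets(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ParameterError("targets must be a 2-D (samples × attributes) array")
    return Y


def select_screen_components(X, Y, cap: int = MAX_SCREEN_COMPONENTS, n_folds: int = 5) -> int:
    """Deterministic grid search for the residual-screen PLS component count.

    Picks the count (1..cap, bounded by rank) minimizing unshuffled K-fold CV
    RMSE averaged over attributes; ties go to the smaller count.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d_targets(Y)
    n = X.shape[0]
    max_comp = min(cap, n - max(2, n // n_folds) - 1, X.shape[1])
    if max_comp < 1:
        raise ParameterError("too few samples for the PLS residual screen")
    folds = KFold(n_splits=n_folds, shuffle=False)
    best = (np.inf, 1)
    for k in range(1, max_comp + 1):
        errors = []
        for train_idx, test_idx in folds.split(X):
            model = PLSRegression(n_components=k, scale=False)
            model.fit(X[train_idx], Y[train_idx])
            pred = model.predict(X[test_idx])
            errors.append(np.mean((pred - Y[test_idx]) ** 2))
        rmse = float(np.sqrt(np.mean(errors)))
        if rmse < best[0] - 1e-12:
            best = (rmse, k)
    return best[1]


def plsr_residuals(X, Y, n_components: int | None = None) -> np.ndarray:
    """Absolute residuals |y − ŷ| of per-attribute PLS1 fits on all samples.

    One single-task PLS model per attribute, fitted to the full data
    (centering only, no scaling). ``n_components=None`` triggers the
    deterministic CV grid search (cap 15).
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d_targets(Y)
    if X.shape[0] != Y.shape[0]:
        raise ParameterError("X and Y must have the same number of samples")
    if n_components is None:
        n_components = select_screen_components(X, Y)
    if n_components < 1 or n_components > min(X.shape[0] - 1, X.shape[1]):
        raise ParameterError(
            f"n_components={n_components} out of range; use 1..{min(X.shape[0]-1, X.shape[1])} "
            "(fewer components for rank-deficient spectra)"
        )
    residuals = np.empty_like(Y)
    for j in range(Y.shape[1]):
        model = PLSRegression(n_components=n_components, scale=False)
        model.fit(X, Y[:, j])
        residuals[:, j] = np.abs(Y[:, j] - model.predict(X).ravel())
    return residuals


@dataclass
class OutlierReport:
    """Residuals, thresholds and flags of the union-rule outlier screen."""

    residuals: np.ndarray  # n × k absolute residuals
    thresholds: np.ndarray  # k per-attribute thresholds
    flags: np.ndarray  # n × k boolean
    union_flags: np.ndarray  # n boolean: flagged on any attribute

    @property
    def removed_count(self) -> int:
        return int(self.union_flags.sum())

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.union_flags)


def auto_thresholds(residuals, n_sd: float = 3.0) -> np.ndarray:
    """Reproducible default: mean + 3·SD of each attribute's residuals."""
    residuals = np.asarray(residuals, dtype=float)
    return residuals.mean(axis=0) + n_sd * residuals.std(axis=0, ddof=1)


def flag_outliers(residuals, thresholds) -> OutlierReport:
    """Apply per-attribute thresholds and the multi-task union rule.

    A sample flagged on any one attribute is removed from all attributes.
    Thresholds may be +inf (vacuous) but must be positive.
    """
    residuals = np.asarray(residuals, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if residuals.ndim != 2 or thresholds.shape != (residuals.shape[1],):
        raise ParameterError("thresholds must provide one value per attribute")
    if np.any(thresholds <= 0) or np.any(np.isnan(thresholds)):
        raise ParameterError("outlier thresholds must be positive")
    flags = residuals > thresholds
    return OutlierReport(residuals, thresholds, flags, flags.any(axis=1))


def screen_outliers(X, Y, thresholds=None, n_components: int | None = None) -> OutlierReport:
    """plsr_residuals + flag_outliers in one call (thresholds=None → auto)."""
    residuals = plsr_residuals(X, Y, n_components)
    if thresholds is None:
        thresholds = auto_thresholds(residuals)
    return flag_outliers(residuals, thresholds)


@dataclass(frozen=True)
class SplitAssignment:
    """3:1:1 train/validation/test partition of the retained samples."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int

    def as_dict(self) -> dict:
        return {
            "train": self.train.tolist(),
            "val": self.val.tolist(),
            "test": self.test.tolist(),
            "seed": self.seed,
        }


def split_dataset(n_retained: int, seed: int = 0) -> SplitAssignment:
    """Random 3:1:1 split: ~60% train, ~20% validation, remainder test.

    Sizes are nearest-integer rounded (train then validation), so n=100 →
    60/20/20 and n=101 → 61/20/20. Identical for a fixed seed; the same
    assignment serves both single- and multi-task models.
    """
    if n_retained < 5:
        raise ParameterError(f"need at least 5 retained samples to split 3:1:1, got {n_retained}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_retained)
    n_train = int(np.floor(0.6 * n_retained + 0.5))
    n_val = int(np.floor(0.2 * n_retained + 0.5))
    n_train = min(n_train, n_retained - 2)
    n_val = max(1, min(n_val, n_retained - n_train - 1))
    return SplitAssignment(
        train=np.sort(order[:n_train]),
        val=np.sort(order[n_train : n_train + n_val]),
        test=np.sort(order[n_train + n_val :]),
        seed=seed,
    )
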