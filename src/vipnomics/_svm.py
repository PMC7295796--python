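"""Shared cross-validation and linear-SVC plumbing.

One classifier family is used across the whole pipeline: a soft-margin
support vector classifier with a linear kernel (libsvm via scikit-learn,
matching the R e1071 backend), default cost 0.25.  Repeated stratified
k-fold splits are seeded so every stage is reproducible, and per-stage
sub-seeds are derived from the master seed by a counter-based scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "DEFAULT_COST",
    "CvSpec",
    "StratificationError",
    "derive_seed",
    "fit_linear_svc",
    "fold_standardize",
]

DEFAULT_COST = 0.25


class StratificationError(ValueError):
    """A class is too small for stratified folds (a fold would be pure)."""


def derive_seed(master: int, *key: int) -> int:
    """Deterministic sub-seed from a master seed and an integer key path."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class CvSpec:
    """Repeated stratified k-fold specification."""

    folds: int = 5
    repeats: int = 20
    seed: int = 0

    @property
    def n_splits_total(self) -> int:
        return self.folds * self.repeats

    def split(self, y: np.ndarray):
        """Yield (repeat, fold, train_idx, test_idx) tuples."""
        y = np.asarray(y)
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < self.folds:
            raise StratificationError(
                f"smallest class has {counts.min()} samples; cannot form "
                f"{self.folds} stratified folds with both classes present"
            )
        rskf = RepeatedStratifiedKFold(
            n_splits=self.folds, n_repeats=self.repeats, random_state=self.seed
        )
        for i, (tr, te) in enumerate(rskf.split(np.zeros_like(y), y)):
            yield i // self.folds, i % self.folds, tr, te


def fit_linear_svc(x: np.ndarray, y: np.ndarray, cost: float = DEFAULT_COST) -> SVC:
    clf = SVC(kernel="linear", C=cost)
    clf.fit(x, y)
    return clf


def fold_standardize(
    x_train: np.ndarray, x_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize with training-fold statistics (zero-variance scale -> 1)."""
    center = x_train.mean(axis=0)
    scale = x_train.std(axis=0, ddof=1)
    scale = np.where(scale == 0, 1.0, scale)
    return (x_train - center) / scale, (x_test - center) / scale
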