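"""Profile-matrix preprocessing: presence filter, KNN imputation, scaling.

The raw LC-MS feature matrix arrives with intensity-dependent missingness.
Preprocessing follows the order used throughout the pipeline:

1. ``presence_filter`` — discard features not observed in at least 75% of the
   patients of at least one phenotype group (HN or LN);
2. ``log10_transform`` — metabolite intensities span decades and are roughly
   log-normal, so modelling happens on the log10 scale;
3. ``knn_impute`` — feature-wise k-nearest-neighbour imputation of the
   remaining missing cells;
4. ``standardize`` — per-feature centring/scaling (margin classifiers are
   scale-sensitive); the fitted center/scale is stored and re-applied to new
   samples at prediction time.

The KNN variant imputes a missing cell (sample i, feature j) with the mean of
the k features nearest to j — by root-mean-square difference over the samples
where both features are observed — among features observed at sample i.  When
fewer than k such neighbours exist the observed mean of feature j is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import ProfileMatrix, ValidationError

__all__ = [
    "presence_filter",
    "knn_impute",
    "log10_transform",
    "standardize",
    "Standardizer",
    "ParameterError",
]


class ParameterError(ValueError):
    """A tuning parameter is incompatible with the data shape."""


def presence_filter(
    m: ProfileMatrix, min_fraction: float = 0.75
) -> tuple[ProfileMatrix, list[str]]:
    """Keep features observed in >= ``min_fraction`` of at least one group.

    Groups are the overall HN/LN phenotype labels.  Returns the filtered
    matrix (feature order preserved) and the list of dropped feature ids.
    The operation is idempotent.
    """
    groups = sorted(set(m.labels))
    if len(groups) < 2:
        raise ValidationError(
            f"presence filter needs both phenotype groups, found {groups}"
        )
    observed = ~m.missing_mask
    keep = np.zeros(m.n_features, dtype=bool)
    for g in groups:
        rows = np.asarray([l == g for l in m.labels])
        frac = observed[rows].mean(axis=0)
        keep |= frac >= min_fraction
    kept_ids = [f for f, k in zip(m.feature_ids, keep) if k]
    dropped = [f for f, k in zip(m.feature_ids, keep) if not k]
    return m.subset_features(kept_ids), dropped


def log10_transform(m: ProfileMatrix, pseudocount: float = 0.0) -> ProfileMatrix:
    """log10 of the intensities; missing cells stay missing."""
    out = m.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out.values = np.log10(out.values + pseudocount)
    return out


def _neighbour_distances(x: np.ndarray, j: int) -> np.ndarray:
    """RMS difference of feature j to every feature over shared observed samples.

    Normalising by the shared-sample count keeps features with few overlapping
    observations comparable to fully observed ones; features sharing no
    samples with j get distance +inf.
    """
    diff = x - x[:, [j]]
    shared = ~np.isnan(diff)
    counts = shared.sum(axis=0)
    sq = np.where(shared, diff, 0.0) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(sq.sum(axis=0) / counts)
    d[counts == 0] = np.inf
    d[j] = np.inf
    return d


def knn_impute(m: ProfileMatrix, k: int = 10) -> ProfileMatrix:
    """Feature-wise KNN imputation; observed entries are never altered.

    For each feature with missing cells, candidate neighbour features are
    ranked by RMS distance over mutually observed samples; a missing cell is
    filled with the unweighted mean of the k nearest neighbours observed at
    that sample, falling back to the feature's observed mean when fewer than
    k neighbours qualify (or the overall observed mean for an entirely
    missing feature).
    """
    if k >= m.n_features:
        raise ParameterError(
            f"k={k} must be smaller than the number of features ({m.n_features})"
        )
    if k < 1:
        raise ParameterError("k must be >= 1")
    x = m.values
    out = x.copy()
    missing = np.isnan(x)
    if not missing.any():
        return m.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_means = np.nanmean(x, axis=0)
    overall_mean = np.nanmean(x)
    for j in np.flatnonzero(missing.any(axis=0)):
        if missing[:, j].all():
            out[missing[:, j], j] = overall_mean
            continue
        d = _neighbour_distances(x, j)
        order = np.argsort(d, kind="stable")
        for i in np.flatnonzero(missing[:, j]):
            # neighbours must themselves be observed at sample i
            usable = order[~np.isnan(x[i, order]) & np.isfinite(d[order])]
            if len(usable) >= k:
                out[i, j] = x[i, usable[:k]].mean()
            else:
                out[i, j] = col_means[j]
    res = m.copy()
    res.values = out
    return res


@dataclass
class Standardizer:
    """Per-feature center/scale fitted on training data."""

    feature_ids: list[str]
    center: np.ndarray
    scale: np.ndarray

    def transform(self, m: ProfileMatrix) -> ProfileMatrix:
        if m.feature_ids != self.feature_ids:
            raise ValidationError("feature ids do not match the fitted standardizer")
        out = m.copy()
        out.values = (m.values - self.center) / self.scale
        return out

    def transform_array(self, x: np.ndarray) -> np.ndarray:
        return (x - self.center) / self.scale


def standardize(m: ProfileMatrix) -> tuple[ProfileMatrix, Standardizer]:
    """Center each feature to mean 0 and scale to SD 1.

    Requires a fully observed matrix.  Zero-variance features get scale 1
    (their standardized column is all zeros) with a warning.
    """
    if np.isnan(m.values).any():
        raise ValidationError("standardize requires an imputed (complete) matrix")
    center = m.values.mean(axis=0)
    scale = m.values.std(axis=0, ddof=1) if m.n_samples > 1 else np.ones(m.n_features)
    zero = scale == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature(s); scale set to 1",
            stacklevel=2,
        )
        scale = np.where(zero, 1.0, scale)
    std = Standardizer(list(m.feature_ids), center, scale)
    return std.transform(m), std
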