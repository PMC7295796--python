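"""Longitudinal coupled classifier across two treatment time points.

The coupled model classifies the neuropathy response from a linear
combination of two time points' standardized metabolite matrices,

    Y = f(X_t1 + beta * X_t2),

where ``f`` is the pipeline's linear SVC and ``beta`` is a scalar coupling
weight estimated by minimizing the repeated cross-validated misclassification
error of the combined matrix.  When the predictive features of the two time
points are disjoint, adding the second time point cannot help and the
estimated ``beta`` sits near zero regardless of the initial guess — the
signature of time-point-specific biomarker sets.  ``beta = 0`` reduces
exactly to the single-time-point classifier on ``m1``.

The optimizer is derivative-free and reproducible: a grid scan over
``[-2, 2]`` in steps of 0.1 followed by golden-section refinement around the
best bracket, with the same CV folds reused for every ``beta`` so the error
curve is comparable across the grid.  Local refinements are additionally run
from each user-supplied initial guess to expose multi-modality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._svm import DEFAULT_COST, CvSpec, fit_linear_svc, fold_standardize
from .containers import ProfileMatrix, ValidationError

__all__ = ["BetaFit", "fit_beta"]

_GOLDEN = (np.sqrt(5) - 1) / 2


@dataclass
class BetaFit:
    """Result of the scalar coupling estimation between two time points."""

    t1: str
    t2: str
    beta_hat: float
    error_at_beta_hat: float
    error_curve: list[tuple[float, float]]
    per_guess: dict[float, float]
    initial_guesses: list[float]
    seed: int

    def error_spread(self) -> float:
        """max - min cross-validated error over the evaluated grid."""
        errs = [e for _, e in self.error_curve]
        return max(errs) - min(errs)


def _cv_error_factory(x1, x2, y, cv: CvSpec, cost: float):
    """Misclassification-error objective E(beta) with folds fixed once."""
    splits = [(tr, te) for _, _, tr, te in cv.split(y)]
    cache: dict[float, float] = {}

    def err(beta: float) -> float:
        b = float(round(beta, 12))
        if b in cache:
            return cache[b]
        x = x1 + b * x2
        wrong = 0
        total = 0
        for tr, te in splits:
            xtr, xte = fold_standardize(x[tr], x[te])
            clf = fit_linear_svc(xtr, y[tr], cost)
            wrong += int((clf.predict(xte) != y[te]).sum())
            total += len(te)
        cache[b] = wrong / total
        return cache[b]

    return err, cache


def _golden_section(err, lo: float, hi: float, n_iter: int = 25) -> None:
    """Golden-section scan of [lo, hi]; evaluations land in the err cache."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = err(c), err(d)
    for _ in range(n_iter):
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = err(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = err(d)


def fit_beta(
    m1: ProfileMatrix,
    m2: ProfileMatrix,
    labels: list[str] | None = None,
    beta_grid: np.ndarray | None = None,
    initial_guesses: tuple[float, ...] = (-1.0, 0.0, 1.0),
    cv: CvSpec | None = None,
    cost: float = DEFAULT_COST,
    error_tol: float | None = None,
) -> BetaFit:
    """Estimate the scalar coupling ``beta`` between two time points.

    ``m1`` and ``m2`` must share sample ids and feature ids (a common,
    standardized feature space).  ``labels`` defaults to ``m1``'s phenotype
    labels.  Returns the minimizer over all evaluated points (grid plus
    refinements) under a parsimony rule: two ``beta`` values whose CV errors
    differ by at most ``error_tol`` are considered equivalent and the smaller
    ``|beta|`` wins.  The default tolerance is three prediction slots
    (``3 / n_cv_predictions``), the granularity below which error differences
    are fold-assignment noise rather than signal.
    """
    if m1.feature_ids != m2.feature_ids:
        raise ValidationError("time points must share an identical feature set")
    if m1.sample_ids != m2.sample_ids:
        raise ValidationError("time points must share an identical patient set")
    if labels is None:
        labels = m1.labels
    y = np.asarray([1 if l == "HN" else 0 for l in labels])
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValidationError("need at least 2 patients per class")
    if beta_grid is None:
        beta_grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)
    cv = cv or CvSpec(folds=5, repeats=5, seed=0)

    err, cache = _cv_error_factory(m1.values, m2.values, y, cv, cost)
    if error_tol is None:
        error_tol = 3.0 / (len(y) * cv.repeats)
    curve = [(float(b), err(b)) for b in beta_grid]

    def _argmin(pool: dict[float, float]) -> float:
        """Parsimonious minimizer: smallest |beta| within error_tol of the min."""
        floor = min(pool.values())
        near = [b for b, e in pool.items() if e <= floor + error_tol]
        return min(near, key=lambda b: (abs(b), b))

    step = float(np.min(np.diff(beta_grid))) if len(beta_grid) > 1 else 0.1
    best_grid = _argmin(dict(curve))
    _golden_section(err, best_grid - step, best_grid + step)

    per_guess: dict[float, float] = {}
    for g in initial_guesses:
        # descend on the grid from the nearest grid point to a local minimum,
        # treating error differences within error_tol as ties broken toward
        # smaller |beta|, then refine the final bracket
        i = int(np.argmin(np.abs(beta_grid - g)))
        visited = {i}
        while True:
            here_b = float(beta_grid[i])
            here_e = err(here_b)
            move = None
            for j in (i - 1, i + 1):
                if not (0 <= j < len(beta_grid)) or j in visited:
                    continue
                b, e = float(beta_grid[j]), err(float(beta_grid[j]))
                better = e < here_e - error_tol
                tied_closer = abs(e - here_e) <= error_tol and abs(b) < abs(here_b)
                if better or tied_closer:
                    if move is None or (err(float(beta_grid[move])), abs(float(beta_grid[move]))) > (e, abs(b)):
                        move = j
            if move is None:
                break
            i = move
            visited.add(i)
        lo = float(beta_grid[max(i - 1, 0)])
        hi = float(beta_grid[min(i + 1, len(beta_grid) - 1)])
        _golden_section(err, lo, hi)
        local = {b: e for b, e in cache.items() if lo - 1e-9 <= b <= hi + 1e-9}
        per_guess[float(g)] = _argmin(local)

    beta_hat = _argmin(cache)
    return BetaFit(
        t1=m1.timepoint,
        t2=m2.timepoint,
        beta_hat=float(beta_hat),
        error_at_beta_hat=cache[beta_hat],
        error_curve=curve,
        per_guess=per_guess,
        initial_guesses=list(initial_guesses),
        seed=cv.seed,
    )
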