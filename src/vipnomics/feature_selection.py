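"""SVM-RFE metabolite selection with repeated cross-validation.

Recursive feature elimination over a linear SVC: within every resample of a
repeated stratified 5-fold split, the classifier is fitted on the training
fold, features are ranked by absolute weight, the lowest-ranked features are
dropped down to the next candidate subset size (re-ranking at each retained
size), and each size's held-out AUROC, sensitivity and specificity are
recorded.  Subset sizes 1-50 are evaluated alongside the full feature set.
The chosen size maximizes the mean held-out AUROC, and the reported feature
set comes from replaying the elimination trajectory on the full data.

Because a single RFE run is itself a random variable of the fold assignment,
:func:`rfe_ensemble` repeats the whole procedure with independent derived
seeds and keeps the iteration with the highest AUROC, breaking ties by the
lowest specificity standard deviation.  :func:`bootstrap_final_fit` reports
the final model-fitting metric convention: out-of-bag performance over
bootstrap resamples at the selected subset size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._svm import DEFAULT_COST, CvSpec, derive_seed, fit_linear_svc, fold_standardize
from .containers import ProfileMatrix
from .preprocessing import ParameterError

__all__ = [
    "RfeResult",
    "RfeEnsemble",
    "rfe_once",
    "rfe_ensemble",
    "bootstrap_final_fit",
    "intersect_selections",
]


@dataclass
class RfeResult:
    """Cross-validated per-size performance plus the selected feature set."""

    performance: pd.DataFrame
    chosen_size: int
    selected_features: list[str]
    iteration: int
    seed: int

    @property
    def auroc(self) -> float:
        """Mean held-out AUROC at the chosen subset size."""
        row = self.performance.loc[self.performance["size"] == self.chosen_size]
        return float(row["auroc_mean"].iloc[0])

    @property
    def spec_sd(self) -> float:
        row = self.performance.loc[self.performance["size"] == self.chosen_size]
        return float(row["spec_sd"].iloc[0])


@dataclass
class RfeEnsemble:
    """Independent RFE iterations plus the winning one."""

    results: list[RfeResult]
    winner_index: int

    @property
    def winner(self) -> RfeResult:
        return self.results[self.winner_index]


def _sizes_to_evaluate(sizes, n_features: int, include_full: bool) -> list[int]:
    out = sorted({int(s) for s in sizes if 1 <= int(s) <= n_features})
    if include_full and n_features not in out:
        out.append(n_features)
    if not out:
        raise ParameterError("no valid subset sizes to evaluate")
    return out


def _rfe_path(x: np.ndarray, y: np.ndarray, sizes_desc: list[int], cost: float):
    """Yield (size, fitted_clf, feature_indices) along the elimination path."""
    current = np.arange(x.shape[1])
    w = None
    if sizes_desc and sizes_desc[0] < len(current):
        # initial ranking fit on the full feature set
        w = fit_linear_svc(x, y, cost).coef_.ravel()
    for s in sizes_desc:
        if s < len(current):
            order = np.argsort(-np.abs(w), kind="stable")
            current = current[order[:s]]
        clf = fit_linear_svc(x[:, current], y, cost)
        w = clf.coef_.ravel()
        yield s, clf, current


def rfe_once(
    m: ProfileMatrix,
    sizes=range(1, 51),
    cv: CvSpec | None = None,
    cost: float = DEFAULT_COST,
    seed: int = 0,
    iteration: int = 0,
    include_full: bool = True,
) -> RfeResult:
    """One RFE run with repeated stratified 5-fold x 20 cross-validation.

    Standardization is refitted inside every training fold so no held-out
    information leaks into the ranking.  The chosen size maximizes mean
    held-out AUROC (ties toward the smaller, more parsimonious size).
    """
    cv = cv or CvSpec(folds=5, repeats=20, seed=seed)
    y = m.y()
    sizes_eval = _sizes_to_evaluate(sizes, m.n_features, include_full)
    sizes_desc = sorted(sizes_eval, reverse=True)

    records: dict[int, dict[str, list[float]]] = {
        s: {"auroc": [], "sens": [], "spec": []} for s in sizes_eval
    }
    for _, _, tr, te in cv.split(y):
        xtr, xte = fold_standardize(m.values[tr], m.values[te])
        for s, clf, feats in _rfe_path(xtr, y[tr], sizes_desc, cost):
            dec = clf.decision_function(xte[:, feats])
            pred = clf.predict(xte[:, feats])
            records[s]["auroc"].append(roc_auc_score(y[te], dec))
            pos = y[te] == 1
            records[s]["sens"].append(float((pred[pos] == 1).mean()))
            records[s]["spec"].append(float((pred[~pos] == 0).mean()))

    rows = []
    for s in sizes_eval:
        r = records[s]
        rows.append(
            {
                "size": s,
                "auroc_mean": float(np.mean(r["auroc"])),
                "auroc_sd": float(np.std(r["auroc"], ddof=1)),
                "sens_mean": float(np.mean(r["sens"])),
                "sens_sd": float(np.std(r["sens"], ddof=1)),
                "spec_mean": float(np.mean(r["spec"])),
                "spec_sd": float(np.std(r["spec"], ddof=1)),
            }
        )
    perf = pd.DataFrame(rows)
    chosen = int(
        min(
            sizes_eval,
            key=lambda s: (-perf.loc[perf["size"] == s, "auroc_mean"].iloc[0], s),
        )
    )

    # Replay the elimination trajectory on the full (standardized) data to
    # name the selected features, ranked by final absolute weight.
    xs, _ = fold_standardize(m.values, m.values)
    selected: list[str] = []
    for s, clf, feats in _rfe_path(xs, y, sizes_desc, cost):
        if s == chosen:
            order = np.argsort(-np.abs(clf.coef_.ravel()), kind="stable")
            selected = [m.feature_ids[j] for j in feats[order]]
            break
    return RfeResult(perf, chosen, selected, iteration, cv.seed)


def rfe_ensemble(
    m: ProfileMatrix,
    n_iter: int = 100,
    sizes=range(1, 51),
    cv_folds: int = 5,
    cv_repeats: int = 20,
    cost: float = DEFAULT_COST,
    seed: int = 0,
    include_full: bool = True,
) -> RfeEnsemble:
    """Repeat RFE ``n_iter`` times with derived seeds and pick the winner.

    Winner criterion: highest mean AUROC at the chosen size (compared at 1e-4
    resolution), ties broken by the lowest specificity SD, then by iteration
    order.
    """
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    results = []
    for i in range(n_iter):
        sub = derive_seed(seed, 1, i)
        cv = CvSpec(folds=cv_folds, repeats=cv_repeats, seed=sub)
        results.append(
            rfe_once(m, sizes, cv, cost, iteration=i, include_full=include_full)
        )
    winner = min(
        range(n_iter),
        key=lambda i: (-round(results[i].auroc / 1e-4), results[i].spec_sd, i),
    )
    return RfeEnsemble(results, winner)


def bootstrap_final_fit(
    m: ProfileMatrix,
    features: list[str],
    n_boot: int = 25,
    cost: float = DEFAULT_COST,
    seed: int = 0,
) -> dict[str, float]:
    """Out-of-bag performance of the selected feature set over bootstraps.

    Each resample draws n samples with replacement, fits the SVC on the
    resample (standardized by resample statistics) and scores the out-of-bag
    samples.  Resamples whose training or out-of-bag part lacks a class are
    redrawn.  Returns mean and SD of AUROC, sensitivity and specificity.
    """
    if not features:
        raise ParameterError("empty feature set")
    sub = m.subset_features(features)
    y = sub.y()
    n = sub.n_samples
    rng = np.random.default_rng(seed)
    aurocs, senss, specs = [], [], []
    for _ in range(n_boot):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if len(np.unique(y[idx])) == 2 and len(np.unique(y[oob])) == 2:
                break
        else:  # pragma: no cover - pathological class balance
            raise ParameterError("could not draw a usable bootstrap resample")
        xtr, xte = fold_standardize(sub.values[idx], sub.values[oob])
        clf = fit_linear_svc(xtr, y[idx], cost)
        dec = clf.decision_function(xte)
        pred = clf.predict(xte)
        pos = y[oob] == 1
        aurocs.append(roc_auc_score(y[oob], dec))
        senss.append(float((pred[pos] == 1).mean()))
        specs.append(float((pred[~pos] == 0).mean()))
    return {
        "auroc_mean": float(np.mean(aurocs)),
        "auroc_sd": float(np.std(aurocs, ddof=1)),
        "sens_mean": float(np.mean(senss)),
        "sens_sd": float(np.std(senss, ddof=1)),
        "spec_mean": float(np.mean(specs)),
        "spec_sd": float(np.std(specs, ddof=1)),
    }


def intersect_selections(a: list[str], b: list[str]) -> list[str]:
    """Order-preserving intersection (order of ``a``); warns when empty."""
    bset = set(b)
    out = [f for f in a if f in bset]
    if not out:
        warnings.warn("selected feature lists are disjoint", stacklevel=2)
    return out
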