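"""Final per-time-point model training and decision support.

Given the selected metabolites for one time point, :func:`tune_and_train`
tunes the SVC cost over ten successive doublings of 0.25 by repeated
stratified 5-fold x 20 cross-validation (AUROC as the tuning metric), refits
on the full data at the winning cost, and calibrates probabilities by Platt
(sigmoid) scaling fitted on the pooled cross-validated decision values.

Because the cohort is unbalanced (2:1 HN:LN), a default probability cutoff
of 0.5 biases predictions toward HN; :func:`choose_threshold` scans cutoffs
in [0.5, 1] and picks the one minimizing the distance from the perfect
corner (sensitivity = specificity = 1), also reporting Youden's J.

:func:`predict` applies a trained model to new samples, and
:func:`two_timepoint_decision` implements the dose-decision rule: flag a
patient for possible vincristine dose adjustment only when the day-8 and
month-6 model probabilities both exceed their thresholds (strict >).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from ._svm import DEFAULT_COST, CvSpec, fit_linear_svc, fold_standardize
from .containers import ProfileMatrix, ValidationError

__all__ = [
    "TrainedModel",
    "CvPredictions",
    "SchemaError",
    "default_cost_grid",
    "tune_and_train",
    "choose_threshold",
    "predict",
    "two_timepoint_decision",
]


class SchemaError(ValueError):
    """New-sample input lacks features the model requires."""


def default_cost_grid(base: float = DEFAULT_COST, length: int = 10) -> list[float]:
    """Successive doublings of the base cost: 0.25, 0.5, ..., 128."""
    return [base * 2**k for k in range(length)]


@dataclass
class TrainedModel:
    """A per-time-point linear SVC in standardized feature space.

    Probabilities are ``1 / (1 + exp(A*d + B))`` of the decision value ``d``;
    a sample is flagged HN when the probability strictly exceeds
    ``threshold``.
    """

    timepoint: str
    feature_ids: list[str]
    center: np.ndarray
    scale: np.ndarray
    weights: np.ndarray
    intercept: float
    cost: float
    calib_a: float
    calib_b: float
    threshold: float = 0.5
    cv_auroc: float = float("nan")

    def decision(self, x: np.ndarray) -> np.ndarray:
        xs = (np.asarray(x, dtype=float) - self.center) / self.scale
        return xs @ self.weights + self.intercept

    def probability(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision(x), self.calib_a, self.calib_b)

    # ------------------------------------------------------------------- i/o
    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema": "vipnomics.trained_model/1",
            "timepoint": self.timepoint,
            "feature_ids": self.feature_ids,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "cost": self.cost,
            "calib_a": self.calib_a,
            "calib_b": self.calib_b,
            "threshold": self.threshold,
            "cv_auroc": self.cv_auroc,
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        return cls(
            timepoint=d["timepoint"],
            feature_ids=list(d["feature_ids"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            cost=float(d["cost"]),
            calib_a=float(d["calib_a"]),
            calib_b=float(d["calib_b"]),
            threshold=float(d["threshold"]),
            cv_auroc=float(d["cv_auroc"]),
        )


@dataclass
class CvPredictions:
    """Held-out probabilities per (repeat, fold, sample)."""

    table: pd.DataFrame  # columns: repeat, fold, sample_id, y_true, decision, probability

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.table["y_true"].to_numpy(),
            self.table["probability"].to_numpy(dtype=float),
        )


def _sigmoid(decision: np.ndarray, a: float, b: float) -> np.ndarray:
    z = a * np.asarray(decision, dtype=float) + b
    return expit(-z)


def _platt_fit(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt's sigmoid calibration with prior-corrected targets."""
    d = np.asarray(decision, dtype=float)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab):
        a, b = ab
        z = a * d + b
        # log p = -log(1+e^z); log(1-p) = z - log(1+e^z)
        log1pez = np.logaddexp(0.0, z)
        return float(np.sum(t * log1pez - (1 - t) * (z - log1pez)))

    b0 = np.log((n_neg + 1.0) / (n_pos + 1.0))
    res = minimize(nll, x0=np.array([-1.0, b0]), method="BFGS")
    a, b = res.x
    return float(a), float(b)


def tune_and_train(
    m: ProfileMatrix,
    cost_grid: list[float] | None = None,
    cv: CvSpec | None = None,
    seed: int = 0,
) -> tuple[TrainedModel, CvPredictions]:
    """Tune the SVC cost by repeated CV and refit on the full data.

    The cost maximizing mean held-out AUROC wins; ties go to the smallest
    cost (strongest regularization).  The returned :class:`CvPredictions`
    carry each sample's held-out decision value per repeat, mapped through
    the pooled Platt sigmoid.
    """
    cost_grid = cost_grid or default_cost_grid()
    cv = cv or CvSpec(folds=5, repeats=20, seed=seed)
    y = m.y()
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValidationError("need at least 2 samples per class")

    fold_records: dict[float, list[dict]] = {c: [] for c in cost_grid}
    mean_auroc: dict[float, float] = {}
    for cost in cost_grid:
        aurocs = []
        for rep, fold, tr, te in cv.split(y):
            xtr, xte = fold_standardize(m.values[tr], m.values[te])
            clf = fit_linear_svc(xtr, y[tr], cost)
            dec = clf.decision_function(xte)
            aurocs.append(roc_auc_score(y[te], dec))
            fold_records[cost].append(
                {"repeat": rep, "fold": fold, "test": te, "decision": dec}
            )
        mean_auroc[cost] = float(np.mean(aurocs))
    best_cost = min(cost_grid, key=lambda c: (-round(mean_auroc[c] / 1e-10), c))

    rows = []
    for rec in fold_records[best_cost]:
        for i, d in zip(rec["test"], rec["decision"]):
            rows.append(
                {
                    "repeat": rec["repeat"],
                    "fold": rec["fold"],
                    "sample_id": m.sample_ids[i],
                    "y_true": int(y[i]),
                    "decision": float(d),
                }
            )
    cvtab = pd.DataFrame(rows)
    a, b = _platt_fit(cvtab["decision"].to_numpy(), cvtab["y_true"].to_numpy())
    cvtab["probability"] = _sigmoid(cvtab["decision"].to_numpy(), a, b)

    center = m.values.mean(axis=0)
    scale = m.values.std(axis=0, ddof=1)
    scale = np.where(scale == 0, 1.0, scale)
    clf = fit_linear_svc((m.values - center) / scale, y, best_cost)
    model = TrainedModel(
        timepoint=m.timepoint,
        feature_ids=list(m.feature_ids),
        center=center,
        scale=scale,
        weights=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        cost=float(best_cost),
        calib_a=a,
        calib_b=b,
        cv_auroc=mean_auroc[best_cost],
    )
    return model, CvPredictions(cvtab)


def choose_threshold(
    p: CvPredictions, grid: np.ndarray | None = None
) -> tuple[float, pd.DataFrame]:
    """Pick the probability cutoff closest to the perfect corner.

    Scans the grid (default 0.5..1.0 step 0.01); at each cutoff a sample is
    called HN when its probability strictly exceeds it.  Minimizes
    sqrt((1-sens)^2 + (1-spec)^2); ties go to the lowest cutoff.  Youden's
    J = sens + spec - 1 is reported alongside.
    """
    if grid is None:
        grid = np.round(np.arange(0.50, 1.0 + 1e-9, 0.01), 10)
    y, prob = p.pooled()
    if len(np.unique(y)) < 2:
        raise ValidationError(
            "cross-validated predictions contain a single class; "
            "sensitivity/specificity are undefined"
        )
    pos = y == 1
    rows = []
    for thr in grid:
        pred = prob > thr
        sens = float(pred[pos].mean())
        spec = float((~pred[~pos]).mean())
        rows.append(
            {
                "threshold": float(thr),
                "sensitivity": sens,
                "specificity": spec,
                "youden_j": sens + spec - 1.0,
                "distance": float(np.hypot(1 - sens, 1 - spec)),
            }
        )
    curve = pd.DataFrame(rows)
    best = int(curve["distance"].idxmin())  # first minimum -> lowest threshold
    return float(curve.loc[best, "threshold"]), curve


def predict(
    model: TrainedModel, new_samples: pd.DataFrame | ProfileMatrix
) -> pd.DataFrame:
    """Per-sample HN probability and flag for new data.

    Input columns must include every model feature (extra columns are
    ignored); absent features raise :class:`SchemaError` naming them.
    """
    if isinstance(new_samples, ProfileMatrix):
        df = pd.DataFrame(
            new_samples.values,
            columns=new_samples.feature_ids,
            index=new_samples.sample_ids,
        )
    else:
        df = new_samples
    missing = [f for f in model.feature_ids if f not in df.columns]
    if missing:
        raise SchemaError(f"input lacks model features: {missing}")
    x = df[model.feature_ids].to_numpy(dtype=float)
    prob = model.probability(x)
    return pd.DataFrame(
        {
            "sample_id": list(df.index),
            "probability": prob,
            "hn_flag": prob > model.threshold,
        }
    )


def two_timepoint_decision(
    p_day8: float, p_month6: float, thresholds: tuple[float, float] = (0.7, 0.7)
) -> str:
    """Dose-decision rule over the day-8 and month-6 model outputs.

    Returns ``"consider-dose-adjustment"`` only when both probabilities
    strictly exceed their thresholds, else ``"no-flag"``.
    """
    if p_day8 > thresholds[0] and p_month6 > thresholds[1]:
        return "consider-dose-adjustment"
    return "no-flag"
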