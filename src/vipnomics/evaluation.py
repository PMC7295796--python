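"""Confusion-matrix metrics and ROC/AUROC.

:func:`confusion_metrics` produces the full clinical-classification metric
suite for a binary HN/LN prediction task (positive class = HN): accuracy with
an exact Clopper-Pearson 95% CI, the no-information rate (NIR) and the
one-sided exact binomial test of accuracy > NIR, Cohen's kappa, McNemar's
chi-square test with continuity correction, sensitivity/specificity, predictive
values, prevalence, detection rate/prevalence, and balanced accuracy.

:func:`roc_auroc` builds the ROC curve over all probability cut points and
integrates it by the trapezoid rule; the result equals the normalized
Mann-Whitney concordance statistic (ties counted 1/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import binomtest
from sklearn.metrics import roc_curve
from statsmodels.stats.contingency_tables import mcnemar as _mcnemar

from .containers import ValidationError

__all__ = ["ConfusionSummary", "RocCurve", "confusion_metrics", "roc_auroc"]


@dataclass
class ConfusionSummary:
    """2x2 counts plus the derived metric suite (positive class = HN)."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    accuracy_ci: tuple[float, float]
    nir: float
    p_acc_gt_nir: float
    kappa: float
    mcnemar_p: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    prevalence: float
    detection_rate: float
    detection_prevalence: float
    balanced_accuracy: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        d = asdict(self)
        d["accuracy_ci"] = list(self.accuracy_ci)
        return d

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int) -> "ConfusionSummary":
        """Compute every metric from the 2x2 counts alone."""
        n = tp + fp + fn + tn
        if n == 0:
            raise ValidationError("empty confusion matrix")
        acc = (tp + tn) / n
        ci = binomtest(tp + tn, n).proportion_ci(
            confidence_level=0.95, method="exact"
        )
        prevalence = (tp + fn) / n
        nir = max(prevalence, 1 - prevalence)
        p_acc = binomtest(tp + tn, n, p=nir, alternative="greater").pvalue
        det_prev = (tp + fp) / n
        expected = prevalence * det_prev + (1 - prevalence) * (1 - det_prev)
        kappa = (acc - expected) / (1 - expected) if expected < 1 else 1.0
        if fp + fn > 0:
            mcnemar_p = float(
                _mcnemar([[tp, fp], [fn, tn]], exact=False, correction=True).pvalue
            )
        else:
            mcnemar_p = math.nan
        sens = tp / (tp + fn) if tp + fn else math.nan
        spec = tn / (tn + fp) if tn + fp else math.nan
        ppv = tp / (tp + fp) if tp + fp else math.nan
        npv = tn / (tn + fn) if tn + fn else math.nan
        return cls(
            tp=tp,
            fp=fp,
            fn=fn,
            tn=tn,
            accuracy=acc,
            accuracy_ci=(ci.low, ci.high),
            nir=nir,
            p_acc_gt_nir=p_acc,
            kappa=kappa,
            mcnemar_p=mcnemar_p,
            sensitivity=sens,
            specificity=spec,
            ppv=ppv,
            npv=npv,
            prevalence=prevalence,
            detection_rate=tp / n,
            detection_prevalence=det_prev,
            balanced_accuracy=(sens + spec) / 2,
        )


def _as_binary(labels, positive) -> np.ndarray:
    arr = np.asarray(labels)
    classes = np.unique(arr)
    if len(classes) > 2:
        raise ValidationError(
            f"labels are not binary: {[str(c) for c in classes]}"
        )
    if arr.dtype.kind in "UO":
        return (arr == positive).astype(int)
    if not set(classes.tolist()) <= {0, 1}:
        raise ValidationError(f"numeric labels must be 0/1, got {classes.tolist()}")
    return arr.astype(int) if positive in (1, "HN") else 1 - arr.astype(int)


def confusion_metrics(
    y_true, y_pred, positive="HN"
) -> ConfusionSummary:
    """Full metric suite from true and predicted labels.

    Labels may be strings (``"HN"``/``"LN"``) or already-binary values with
    ``positive`` naming the positive class.
    """
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValidationError(
            f"length mismatch: {t.shape[0]} true vs {p.shape[0]} predicted"
        )
    tb = _as_binary(t, positive)
    pb = _as_binary(p, positive)
    tp = int(((tb == 1) & (pb == 1)).sum())
    fp = int(((tb == 0) & (pb == 1)).sum())
    fn = int(((tb == 1) & (pb == 0)).sum())
    tn = int(((tb == 0) & (pb == 0)).sum())
    return ConfusionSummary.from_counts(tp, fp, fn, tn)


@dataclass
class RocCurve:
    """ROC points from (0,0) to (1,1) plus the trapezoid AUROC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float

    def bootstrap_auroc_ci(
        self, y_true, probs, n_boot: int = 2000, seed: int = 0, level: float = 0.95
    ) -> tuple[float, float]:
        """Percentile bootstrap CI for the AUROC (resampling samples)."""
        y = np.asarray(y_true)
        p = np.asarray(probs, dtype=float)
        rng = np.random.default_rng(seed)
        stats = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(y), size=len(y))
            if len(np.unique(y[idx])) < 2:
                continue
            stats.append(roc_auroc(y[idx], p[idx]).auroc)
        lo, hi = np.quantile(stats, [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)


def roc_auroc(y_true, probs) -> RocCurve:
    """ROC curve and trapezoid AUROC for binary labels (1/"HN" positive)."""
    y = np.asarray(y_true)
    if y.dtype.kind in "UO":
        y = (y == "HN").astype(int)
    p = np.asarray(probs, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC needs at least one sample of each class")
    fpr, tpr, thr = roc_curve(y, p)
    auroc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr, tpr, thr, auroc)
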