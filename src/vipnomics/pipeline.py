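"""End-to-end analysis driver tying the modules together.

``run_fit`` executes, per time point: phenotype labelling from the TNS(c)-PV
trajectories (medium patients excluded), presence filtering, log10 transform,
KNN imputation, the RFE ensemble, bootstrap evaluation of the selected set,
final cost-tuned training with Platt calibration, probability-threshold
optimization, and the confusion-metric suite on the pooled cross-validated
predictions.  ``run_structure`` performs the cross-time-point analyses:
Ward clustering of the stacked profiles and the pairwise longitudinal
coupling (beta) estimation.

All artifacts are plain text (JSON/CSV/Newick) and every stage derives its
seed from the single master seed, so a rerun with the same inputs and seed
reproduces the outputs byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import clustering, feature_selection, longitudinal, phenotyping, preprocessing
from ._svm import DEFAULT_COST, CvSpec, derive_seed
from .containers import ProfileMatrix, TnsTrajectory
from .evaluation import confusion_metrics
from .training import choose_threshold, tune_and_train

__all__ = ["PipelineConfig", "run_fit", "run_structure", "label_matrices"]


@dataclass
class PipelineConfig:
    """All pipeline tunables, pre-filled with the reference defaults."""

    min_fraction: float = 0.75
    knn_k: int = 10
    log_transform: bool = True
    rfe_size_max: int = 50
    rfe_n_iter: int = 100
    cv_folds: int = 5
    cv_repeats: int = 20
    cost: float = DEFAULT_COST
    cost_tune_length: int = 10
    n_boot: int = 25
    threshold_step: float = 0.01
    beta_cv_repeats: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))


def label_matrices(
    matrices: list[ProfileMatrix], trajectories: list[TnsTrajectory]
) -> tuple[list[ProfileMatrix], list[phenotyping.PhenotypeLabel]]:
    """Attach trajectory-derived phenotypes and drop MEDIUM patients."""
    labels = [phenotyping.classify_overall(t) for t in trajectories]
    by_id = {l.patient_id: l.overall for l in labels}
    out = []
    for m in matrices:
        relabelled = m.copy()
        relabelled.labels = [by_id.get(s, "") for s in m.sample_ids]
        out.append(relabelled.exclude_medium())
    return out, labels


def _preprocess(
    m: ProfileMatrix, config: PipelineConfig
) -> tuple[ProfileMatrix, list[str]]:
    filtered, dropped = preprocessing.presence_filter(m, config.min_fraction)
    if config.log_transform:
        filtered = preprocessing.log10_transform(filtered)
    imputed = preprocessing.knn_impute(filtered, config.knn_k)
    return imputed, dropped


def run_fit(
    matrices: list[ProfileMatrix],
    trajectories: list[TnsTrajectory],
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """Full fit on labelled cohort data; writes artifacts, returns the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labelled, all_labels = label_matrices(matrices, trajectories)
    summary = phenotyping.cohort_summary(all_labels)

    report: dict = {"cohort": summary, "timepoints": {}}
    for t_idx, m in enumerate(labelled):
        tp = m.timepoint or f"tp{t_idx + 1}"
        pre, dropped = _preprocess(m, config)
        ens = feature_selection.rfe_ensemble(
            pre,
            n_iter=config.rfe_n_iter,
            sizes=range(1, config.rfe_size_max + 1),
            cv_folds=config.cv_folds,
            cv_repeats=config.cv_repeats,
            cost=config.cost,
            seed=derive_seed(config.seed, 10, t_idx),
        )
        win = ens.winner
        boot = feature_selection.bootstrap_final_fit(
            pre,
            win.selected_features,
            n_boot=config.n_boot,
            cost=config.cost,
            seed=derive_seed(config.seed, 20, t_idx),
        )
        final = pre.subset_features(win.selected_features)
        model, cv_preds = tune_and_train(
            final,
            cv=CvSpec(
                folds=config.cv_folds,
                repeats=config.cv_repeats,
                seed=derive_seed(config.seed, 30, t_idx),
            ),
        )
        grid = np.round(
            np.arange(0.5, 1.0 + 1e-9, config.threshold_step), 10
        )
        threshold, curve = choose_threshold(cv_preds, grid)
        model.threshold = threshold
        y, prob = cv_preds.pooled()
        metrics = confusion_metrics(y, (prob > threshold).astype(int), positive=1)

        model.to_json(out / f"model_{tp}.json")
        cv_preds.table.to_csv(out / f"cv_predictions_{tp}.csv", index=False)
        curve.to_csv(out / f"threshold_curve_{tp}.csv", index=False)
        win.performance.to_csv(out / f"rfe_performance_{tp}.csv", index=False)
        (out / f"selected_features_{tp}.txt").write_text(
            "\n".join(win.selected_features) + "\n"
        )
        report["timepoints"][tp] = {
            "n_samples": m.n_samples,
            "n_features_after_filter": pre.n_features,
            "n_features_dropped": len(dropped),
            "predictors": win.chosen_size,
            "auroc": win.auroc,
            "auroc_sd": float(
                win.performance.loc[
                    win.performance["size"] == win.chosen_size, "auroc_sd"
                ].iloc[0]
            ),
            "bootstrap": boot,
            "selected_features": win.selected_features,
            "cost": model.cost,
            "cv_auroc": model.cv_auroc,
            "threshold": threshold,
            "metrics": metrics.as_dict(),
        }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def run_structure(
    matrices: list[ProfileMatrix],
    trajectories: list[TnsTrajectory],
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """Cross-time-point structure: Ward dendrogram + pairwise beta fits."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labelled, _ = label_matrices(matrices, trajectories)

    pre = []
    for m in labelled:
        filtered, _ = preprocessing.presence_filter(m, config.min_fraction)
        if config.log_transform:
            filtered = preprocessing.log10_transform(filtered)
        pre.append(filtered)
    stacked = clustering.stack_timepoints(pre)
    stacked = preprocessing.knn_impute(stacked, config.knn_k)
    dend = clustering.ward_cluster(stacked)
    grouping = {lbl: lbl.split("@")[1] for lbl in dend.leaf_labels}
    purity = clustering.cut_purity(dend, len(labelled), grouping)
    (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")

    beta_fits = {}
    std_mats = []
    for m in pre:
        common = stacked.feature_ids
        imput = preprocessing.knn_impute(m.subset_features(common), config.knn_k)
        std, _ = preprocessing.standardize(imput)
        std_mats.append(std)
    for i in range(len(std_mats)):
        for j in range(i + 1, len(std_mats)):
            fit = longitudinal.fit_beta(
                std_mats[i],
                std_mats[j],
                cv=CvSpec(
                    folds=config.cv_folds,
                    repeats=config.beta_cv_repeats,
                    seed=derive_seed(config.seed, 40, i, j),
                ),
                cost=config.cost,
            )
            beta_fits[f"{fit.t1}+beta*{fit.t2}"] = {
                "beta_hat": fit.beta_hat,
                "cv_error": fit.error_at_beta_hat,
                "per_guess": {str(k): v for k, v in fit.per_guess.items()},
            }
    result = {"timepoint_cluster_purity": purity, "beta": beta_fits}
    (out / "structure.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    return result
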