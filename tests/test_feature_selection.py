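"""SVM-RFE: per-size CV performance, ensemble selection, bootstrap fit."""

import numpy as np
import pytest

from vipnomics._svm import CvSpec, StratificationError
from vipnomics.containers import ProfileMatrix
from vipnomics.feature_selection import (
    bootstrap_final_fit,
    intersect_selections,
    rfe_ensemble,
    rfe_once,
)
from vipnomics.pipeline import label_matrices
from vipnomics.preprocessing import ParameterError, log10_transform, standardize
from vipnomics.synthetic import SyntheticConfig, generate_cohort


def _separable_matrix(n_per_class=10, n_noise=1, seed=0):
    """Feature f_signal separates the classes perfectly; the rest is noise."""
    rng = np.random.default_rng(seed)
    signal = np.concatenate([rng.uniform(5, 6, n_per_class), rng.uniform(1, 2, n_per_class)])
    noise = rng.normal(size=(2 * n_per_class, n_noise))
    values = np.column_stack([signal, noise])
    return ProfileMatrix(
        [f"s{i}" for i in range(2 * n_per_class)],
        ["f_signal"] + [f"f_noise{j}" for j in range(n_noise)],
        values,
        ["HN"] * n_per_class + ["LN"] * n_per_class,
        "day8",
    )


@pytest.fixture(scope="module")
def planted_cohort():
    """36 patients, 5 informative of 500 features, effect size 2 (log scale)."""
    cfg = SyntheticConfig(
        n_hn=24,
        n_ln=12,
        n_features=500,
        n_informative_per_timepoint=5,
        effect_size=2.0,
        missing_rate=0.0,
        seed=2,
    )
    mats, trajs, truth = generate_cohort(cfg)
    labelled, _ = label_matrices(mats, trajs)
    m = log10_transform(labelled[0]).subset_features(labelled[0].feature_ids[:-1])
    return m, set(truth.informative["day8"])


class TestRfeOnce:
    def test_single_discriminative_feature_is_found(self):
        m = _separable_matrix()
        res = rfe_once(m, sizes=[1, 2], cv=CvSpec(5, 4, seed=0))
        assert res.chosen_size == 1
        assert res.selected_features == ["f_signal"]

    def test_rfe_ranking_recovers_planted_set(self, planted_cohort):
        """At the planted subset size, >=4 of the 5 informative features are
        selected and the CV AUROC is >= 0.9."""
        m, informative = planted_cohort
        res = rfe_once(m, sizes=[5], cv=CvSpec(5, 20, seed=0), include_full=False)
        assert len(set(res.selected_features) & informative) >= 4
        assert res.auroc >= 0.9

    def test_chosen_subset_contains_only_planted_features(self, planted_cohort):
        """Model selection over sizes 1..50 may favour a smaller subset, but
        everything it selects is genuinely informative."""
        m, informative = planted_cohort
        res = rfe_once(m, sizes=range(1, 51), cv=CvSpec(5, 20, seed=0))
        assert set(res.selected_features) <= informative
        assert res.auroc >= 0.9

    def test_permuted_labels_auroc_near_chance(self, planted_cohort):
        m, _ = planted_cohort
        rng = np.random.default_rng(4)
        null = m.copy()
        null.labels = list(rng.permutation(m.labels))
        res = rfe_once(null, sizes=[20], cv=CvSpec(5, 10, seed=0),
                       include_full=False)
        assert 0.35 <= res.auroc <= 0.65

    def test_same_seed_identical_result(self):
        m = _separable_matrix(n_noise=5)
        r1 = rfe_once(m, sizes=[1, 2, 4], cv=CvSpec(5, 3, seed=11))
        r2 = rfe_once(m, sizes=[1, 2, 4], cv=CvSpec(5, 3, seed=11))
        assert r1.selected_features == r2.selected_features
        assert np.allclose(
            r1.performance.drop(columns="size"),
            r2.performance.drop(columns="size"),
            atol=1e-10,
        )

    def test_pure_noise_feature_does_not_displace_signal(self):
        m = _separable_matrix(n_noise=1, seed=1)
        m2 = _separable_matrix(n_noise=2, seed=1)
        r1 = rfe_once(m, sizes=[1], cv=CvSpec(5, 3, seed=0), include_full=False)
        r2 = rfe_once(m2, sizes=[1], cv=CvSpec(5, 3, seed=0), include_full=False)
        assert r1.selected_features == r2.selected_features == ["f_signal"]

    def test_metrics_within_bounds(self, planted_cohort):
        m, _ = planted_cohort
        res = rfe_once(m, sizes=[2, 10], cv=CvSpec(5, 3, seed=0))
        perf = res.performance
        for col in ("auroc_mean", "sens_mean", "spec_mean"):
            assert perf[col].between(0, 1).all()
        for col in ("auroc_sd", "sens_sd", "spec_sd"):
            assert (perf[col] >= 0).all()
        assert len(res.selected_features) == res.chosen_size

    def test_tiny_class_raises_stratification_error(self):
        m = _separable_matrix(n_per_class=3)
        with pytest.raises(StratificationError):
            rfe_once(m, sizes=[1], cv=CvSpec(5, 2, seed=0))


class TestRfeEnsemble:
    def test_single_iteration_is_winner(self):
        m = _separable_matrix(n_noise=3)
        ens = rfe_ensemble(m, n_iter=1, sizes=[1, 2], cv_repeats=3, seed=5)
        assert ens.winner_index == 0

    def test_tie_break_prefers_low_specificity_sd(self):
        m = _separable_matrix(n_noise=3)
        ens = rfe_ensemble(m, n_iter=3, sizes=[1, 2], cv_repeats=3, seed=5)
        win = ens.winner
        for r in ens.results:
            assert (round(win.auroc / 1e-4), -win.spec_sd) >= (
                round(r.auroc / 1e-4),
                -r.spec_sd,
            ) or win.auroc > r.auroc

    def test_null_ensemble_winner_exceeds_mean(self):
        """Selection optimism: the winning null-data iteration scores at or
        above the ensemble average (documented bias of winner-take-all)."""
        rng = np.random.default_rng(9)
        m = ProfileMatrix(
            [f"s{i}" for i in range(20)],
            [f"f{j}" for j in range(30)],
            rng.uniform(1, 2, size=(20, 30)),
            ["HN"] * 10 + ["LN"] * 10,
            "day8",
        )
        ens = rfe_ensemble(m, n_iter=3, sizes=[5], cv_repeats=3, seed=1,
                           include_full=False)
        mean_auroc = np.mean([r.auroc for r in ens.results])
        assert ens.winner.auroc >= mean_auroc - 1e-4

    def test_invalid_n_iter(self):
        with pytest.raises(ParameterError):
            rfe_ensemble(_separable_matrix(), n_iter=0)

    def test_drug_concentration_column_not_selected(self):
        """The phenotype-independent vincristine column never carries signal."""
        cfg = SyntheticConfig(
            n_hn=16, n_ln=8, n_features=200, n_informative_per_timepoint=4,
            effect_size=2.5, missing_rate=0.0, seed=6,
        )
        mats, trajs, _ = generate_cohort(cfg)
        labelled, _ = label_matrices(mats, trajs)
        m = log10_transform(labelled[0])  # vincristine_conc still included
        res = rfe_once(m, sizes=range(1, 11), cv=CvSpec(5, 5, seed=0))
        assert "vincristine_conc" not in res.selected_features


class TestBootstrapFinalFit:
    def test_perfectly_separable_auroc_one(self):
        m = _separable_matrix(n_noise=2)
        out = bootstrap_final_fit(m, ["f_signal"], n_boot=10, seed=0)
        assert out["auroc_mean"] == 1.0 and out["auroc_sd"] == 0.0
        assert out["sens_mean"] == 1.0 and out["spec_mean"] == 1.0

    def test_consistent_with_cv_auroc(self, planted_cohort):
        m, informative = planted_cohort
        feats = sorted(informative)
        res = rfe_once(m.subset_features(feats), sizes=[len(feats)],
                       cv=CvSpec(5, 10, seed=0), include_full=False)
        boot = bootstrap_final_fit(m, feats, n_boot=25, seed=0)
        assert abs(boot["auroc_mean"] - res.auroc) <= 0.1

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ParameterError):
            bootstrap_final_fit(_separable_matrix(), [], n_boot=5)


class TestIntersectSelections:
    def test_order_preserving_intersection(self):
        assert intersect_selections(["x", "y", "z"], ["y", "z", "w"]) == ["y", "z"]

    def test_disjoint_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="disjoint"):
            assert intersect_selections(["a"], ["b"]) == []

    def test_identical_lists_unchanged(self):
        assert intersect_selections(["a", "b"], ["b", "a"]) == ["a", "b"]
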