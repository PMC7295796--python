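"""Cost tuning, Platt calibration, threshold choice, prediction rules."""

import numpy as np
import pandas as pd
import pytest

from vipnomics._svm import CvSpec
from vipnomics.containers import ProfileMatrix, ValidationError
from vipnomics.training import (
    CvPredictions,
    SchemaError,
    TrainedModel,
    choose_threshold,
    default_cost_grid,
    predict,
    tune_and_train,
    two_timepoint_decision,
)


def _matrix(n_per_class=10, n_features=3, gap=4.0, seed=0, tp="day8"):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(2 * n_per_class, n_features))
    x[:, 0] = 0.1 * rng.normal(size=2 * n_per_class)
    x[:n_per_class, 0] += gap
    return ProfileMatrix(
        [f"s{i}" for i in range(2 * n_per_class)],
        [f"f{j}" for j in range(n_features)],
        x - x.min() + 1.0,
        ["HN"] * n_per_class + ["LN"] * n_per_class,
        tp,
    )


def _cv_preds(y, prob):
    return CvPredictions(
        pd.DataFrame(
            {
                "repeat": 0,
                "fold": 0,
                "sample_id": [f"s{i}" for i in range(len(y))],
                "y_true": y,
                "decision": np.asarray(prob) * 2 - 1,
                "probability": prob,
            }
        )
    )


def brute_force_threshold(y, prob, grid):
    """Independent exhaustive scan oracle for the distance-to-corner rule."""
    y = np.asarray(y)
    best = None
    for thr in grid:
        pred = np.asarray(prob) > thr
        sens = pred[y == 1].mean()
        spec = (~pred[y == 0]).mean()
        d = np.sqrt((1 - sens) ** 2 + (1 - spec) ** 2)
        if best is None or d < best[1] - 1e-15:
            best = (thr, d)
    return best[0]


class TestTuneAndTrain:
    def test_separable_data_smallest_cost_wins(self):
        m = _matrix()
        model, preds = tune_and_train(m, cv=CvSpec(5, 3, seed=0))
        assert model.cost == 0.25  # AUROC 1 at every cost; tie -> smallest
        assert model.cv_auroc == 1.0
        assert len(model.weights) == m.n_features

    def test_cost_grid_is_ten_doublings(self):
        grid = default_cost_grid()
        assert grid[0] == 0.25 and grid[-1] == 128.0 and len(grid) == 10

    def test_every_sample_predicted_once_per_repeat(self):
        m = _matrix(n_per_class=8)
        _, preds = tune_and_train(m, cv=CvSpec(4, 3, seed=1))
        per_repeat = preds.table.groupby("repeat")["sample_id"].nunique()
        assert (per_repeat == 16).all()
        assert preds.table.groupby("repeat").size().eq(16).all()

    def test_probabilities_in_open_unit_interval_and_monotone(self):
        m = _matrix(gap=2.0, seed=2)
        model, preds = tune_and_train(m, cv=CvSpec(5, 3, seed=2))
        p = preds.table["probability"].to_numpy()
        assert ((p > 0) & (p < 1)).all()
        tab = preds.table.sort_values("decision")
        assert tab["probability"].is_monotonic_increasing

    def test_roundtrip_serialization_bitwise(self, tmp_path):
        m = _matrix(seed=3)
        model, _ = tune_and_train(m, cv=CvSpec(5, 3, seed=3))
        model.threshold = 0.7
        f1, f2 = tmp_path / "m1.json", tmp_path / "m2.json"
        model.to_json(f1)
        TrainedModel.from_json(f1).to_json(f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_degenerate_class_rejected(self):
        m = _matrix(n_per_class=1)
        with pytest.raises(ValidationError):
            tune_and_train(m, cv=CvSpec(5, 2, seed=0))


class TestChooseThreshold:
    def test_cleanly_separated_probabilities_tie_to_lowest(self):
        y = [1] * 6 + [0] * 4
        prob = [0.9] * 6 + [0.1] * 4
        thr, curve = choose_threshold(_cv_preds(y, prob))
        assert thr == 0.5  # distance 0 everywhere in (0.1, 0.9); lowest wins

    def test_probabilities_equal_labels(self):
        y = [1, 0, 1, 0, 1]
        thr, _ = choose_threshold(_cv_preds(y, [1.0, 0.0, 1.0, 0.0, 1.0]))
        assert thr == 0.5

    def test_eight_point_case_matches_brute_force(self):
        y = [1, 1, 1, 1, 1, 0, 0, 0]
        prob = [0.95, 0.8, 0.72, 0.65, 0.55, 0.78, 0.6, 0.4]
        grid = np.round(np.arange(0.5, 1.0 + 1e-9, 0.01), 10)
        thr, curve = choose_threshold(_cv_preds(y, prob), grid)
        assert thr == brute_force_threshold(y, prob, grid)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(8)
        grid = np.round(np.arange(0.5, 1.0 + 1e-9, 0.01), 10)
        for _ in range(200):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            prob = np.round(rng.uniform(size=n), 3)
            thr, _ = choose_threshold(_cv_preds(y, prob), grid)
            assert thr == brute_force_threshold(y, prob, grid)

    def test_curve_reports_youden_j(self):
        y = [1, 1, 0, 0]
        _, curve = choose_threshold(_cv_preds(y, [0.9, 0.8, 0.3, 0.2]))
        assert np.allclose(
            curve["youden_j"], curve["sensitivity"] + curve["specificity"] - 1
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            choose_threshold(_cv_preds([1, 1, 1], [0.9, 0.8, 0.7]))


class TestPredict:
    def _model(self):
        return TrainedModel(
            timepoint="day8",
            feature_ids=["a", "b"],
            center=np.zeros(2),
            scale=np.ones(2),
            weights=np.array([1.0, 0.0]),
            intercept=0.0,
            cost=0.25,
            calib_a=-1.0,
            calib_b=0.0,
            threshold=0.7,
        )

    def test_flag_strictly_above_threshold(self):
        model = self._model()
        # probability 1/(1+exp(-d)); d = logit of target probability
        d_71 = -np.log(1 / 0.71 - 1)
        d_65 = -np.log(1 / 0.65 - 1)
        df = pd.DataFrame({"a": [d_71, d_65], "b": [0.0, 0.0]}, index=["p1", "p2"])
        out = predict(model, df)
        assert out["probability"].tolist() == pytest.approx([0.71, 0.65])
        assert out["hn_flag"].tolist() == [True, False]

    def test_probability_exactly_at_threshold_not_flagged(self):
        model = self._model()
        df = pd.DataFrame({"a": [1.3], "b": [0.0]}, index=["p"])
        model.threshold = float(predict(model, df)["probability"].iloc[0])
        assert not predict(model, df)["hn_flag"].iloc[0]

    def test_extra_columns_ignored_missing_rejected(self):
        model = self._model()
        ok = pd.DataFrame({"b": [0.0], "a": [1.0], "extra": [9.9]}, index=["p"])
        assert len(predict(model, ok)) == 1
        with pytest.raises(SchemaError, match="b"):
            predict(model, pd.DataFrame({"a": [1.0]}, index=["p"]))

    def test_training_samples_smoke(self):
        m = _matrix(seed=4)
        model, _ = tune_and_train(m, cv=CvSpec(5, 3, seed=4))
        df = pd.DataFrame(m.values, columns=m.feature_ids, index=m.sample_ids)
        out = predict(model, df)
        hn_mean = out["probability"][: 10].mean()
        ln_mean = out["probability"][10:].mean()
        assert hn_mean > ln_mean


class TestTwoTimepointDecision:
    @pytest.mark.parametrize(
        "p8,p6,expected",
        [
            (0.8, 0.9, "consider-dose-adjustment"),
            (0.8, 0.6, "no-flag"),
            (0.2, 0.2, "no-flag"),
            (0.7, 0.9, "no-flag"),  # strict inequality at the threshold
        ],
    )
    def test_rule(self, p8, p6, expected):
        assert two_timepoint_decision(p8, p6, (0.7, 0.7)) == expected
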