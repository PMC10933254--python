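import numpy as np
import pandas as pd
import pytest

from copd_engage.features import FEATURE_COLUMNS
from copd_engage.model_eval import (
    SplitPlan,
    auroc,
    average_precision,
    evaluate_by_group,
    predict_scores,
    split_series,
    train_logistic_baseline,
    tune_and_train,
)

FAST_SPACE = {
    "max_depth": ("int", 2, 3),
    "learning_rate": ("log", 0.1, 0.3),
    "max_iter": ("int", 20, 40),
    "min_samples_leaf": ("int", 10, 30),
    "l2_regularization": ("log", 1e-3, 1.0),
}


def toy_instances(n_series=40, rows_per_series=30, *, signal=1.0, seed=0,
                  group="g"):
    """Instance table whose first feature carries `signal` times the label."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_series):
        labels = (rng.random(rows_per_series) < 0.15).astype(int)
        data = {
            "series_id": f"s{i:03d}",
            "group": group,
            "day_offset": np.arange(rows_per_series),
            "label": labels,
        }
        for j, col in enumerate(FEATURE_COLUMNS):
            noise = rng.normal(size=rows_per_series)
            data[col] = noise + (signal * labels if j == 0 else 0.0)
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


class TestSplitSeries:
    def test_75_25(self):
        plan = split_series([f"s{i}" for i in range(100)], seed=1)
        assert len(plan.train_ids) == 75
        assert len(plan.test_ids) == 25

    def test_disjoint(self):
        plan = split_series([f"s{i}" for i in range(40)], seed=2)
        assert not set(plan.train_ids) & set(plan.test_ids)
        assert set(plan.train_ids) | set(plan.test_ids) == {
            f"s{i}" for i in range(40)
        }

    def test_deterministic(self):
        ids = [f"s{i}" for i in range(30)]
        a = split_series(ids, seed=3)
        b = split_series(ids, seed=3)
        assert a == b

    def test_folds_balanced(self):
        plan = split_series([f"s{i}" for i in range(101)], seed=4, k=5)
        sizes = pd.Series(list(plan.folds.values())).value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert set(plan.folds) == set(plan.train_ids)

    def test_too_few_series_errors(self):
        with pytest.raises(ValueError):
            split_series(["a", "b", "c"], k=5)

    def test_overlap_rejected_by_type(self):
        with pytest.raises(ValueError):
            SplitPlan(("a", "b"), ("b",), {"a": 1, "b": 2}, k=5, seed=0)


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc([1, 0, 0, 0], [0.9, 0.1, 0.2, 0.3]) == 1.0

    def test_all_ties_half(self):
        assert auroc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_brute_force_example(self):
        assert auroc([1, 0, 1, 0], [0.8, 0.7, 0.6, 0.5]) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([1, 1], [0.2, 0.3])


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_single_positive_rank_two(self):
        assert average_precision([1, 0], [0.2, 0.8]) == 0.5

    def test_random_scores_near_positive_fraction(self, rng):
        n, p = 20000, 0.1
        labels = (rng.random(n) < p).astype(int)
        scores = rng.random(n)
        assert average_precision(labels, scores) == pytest.approx(p, abs=0.02)

    def test_no_positives_errors(self):
        with pytest.raises(ValueError):
            average_precision([0, 0], [0.2, 0.3])


class TestTuneAndTrain:
    def test_separable_toy_reaches_training_auroc_one(self):
        instances = toy_instances(20, 20, signal=20.0)
        plan = split_series(instances["series_id"].unique(), seed=0)
        trained = tune_and_train(instances, plan, budget=2, seed=0,
                                 search_space=FAST_SPACE)
        train = instances[instances["series_id"].isin(plan.train_ids)]
        assert auroc(train["label"], predict_scores(trained, train)) > 0.999

    def test_budget_one_returns_single_trial(self):
        instances = toy_instances(15, 15)
        plan = split_series(instances["series_id"].unique(), seed=0)
        trained = tune_and_train(instances, plan, budget=1, seed=5,
                                 search_space=FAST_SPACE)
        assert len(trained.trials) == 1
        assert trained.trials.iloc[0].to_dict() == pytest.approx(
            {"trial": 0,
             "oof_average_precision":
                 trained.trials.iloc[0]["oof_average_precision"],
             **trained.best_params}
        )

    def test_deterministic_given_seed(self):
        instances = toy_instances(15, 15)
        plan = split_series(instances["series_id"].unique(), seed=0)
        a = tune_and_train(instances, plan, budget=2, seed=9,
                           search_space=FAST_SPACE)
        b = tune_and_train(instances, plan, budget=2, seed=9,
                           search_space=FAST_SPACE)
        assert a.best_params == b.best_params
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_permuted_labels_give_chance_holdout_auroc(self):
        # features carry no signal: held-out AUROC must sit near 0.5
        instances = toy_instances(60, 40, signal=0.0, seed=3)
        plan = split_series(instances["series_id"].unique(), seed=1)
        trained = tune_and_train(instances, plan, budget=2, seed=2,
                                 search_space=FAST_SPACE)
        test = instances[instances["series_id"].isin(plan.test_ids)]
        assert len(test) >= 500
        value = auroc(test["label"], predict_scores(trained, test))
        assert 0.42 <= value <= 0.58

    def test_single_class_errors(self):
        instances = toy_instances(10, 10)
        instances["label"] = 0
        plan = split_series(instances["series_id"].unique(), seed=0)
        with pytest.raises(ValueError):
            tune_and_train(instances, plan, budget=1, search_space=FAST_SPACE)


class TestLogisticBaseline:
    def test_separable(self):
        instances = toy_instances(20, 20, signal=20.0)
        plan = split_series(instances["series_id"].unique(), seed=0)
        model = train_logistic_baseline(instances, plan)
        train = instances[instances["series_id"].isin(plan.train_ids)]
        assert auroc(train["label"], predict_scores(model, train)) > 0.999

    def test_deterministic(self):
        instances = toy_instances(15, 15)
        plan = split_series(instances["series_id"].unique(), seed=0)
        a = train_logistic_baseline(instances, plan, seed=1)
        b = train_logistic_baseline(instances, plan, seed=1)
        np.testing.assert_allclose(
            a.model.named_steps["clf"].coef_, b.model.named_steps["clf"].coef_
        )

    def test_handles_missing_values(self):
        instances = toy_instances(15, 15)
        col = list(FEATURE_COLUMNS)[1]
        instances.loc[instances.index[::3], col] = np.nan
        plan = split_series(instances["series_id"].unique(), seed=0)
        model = train_logistic_baseline(instances, plan)
        scores = predict_scores(model, instances)
        assert np.isfinite(scores).all()


class TestEvaluateByGroup:
    @pytest.fixture()
    def trained_setup(self):
        instances = toy_instances(40, 25, signal=3.0, seed=1)
        plan = split_series(instances["series_id"].unique(), seed=0)
        trained = tune_and_train(instances, plan, budget=1, seed=0,
                                 search_space=FAST_SPACE)
        test = instances[instances["series_id"].isin(plan.test_ids)].copy()
        return trained, test

    def test_identical_groups_identical_point_metrics(self, trained_setup):
        trained, test = trained_setup
        double = pd.concat(
            [test.assign(group="a"), test.assign(group="b")], ignore_index=True
        )
        report = evaluate_by_group(trained, double, bootstrap_reps=30, seed=0)
        assert len(report) == 2
        a, b = report.iloc[0], report.iloc[1]
        assert a["auroc"] == b["auroc"]
        assert a["average_precision"] == b["average_precision"]

    def test_five_groups_five_rows(self, trained_setup):
        trained, test = trained_setup
        test["group"] = np.tile(list("abcde"), len(test))[: len(test)]
        report = evaluate_by_group(trained, test, bootstrap_reps=10, seed=0)
        assert len(report) == 5

    def test_ci_brackets_point(self, trained_setup):
        trained, test = trained_setup
        report = evaluate_by_group(trained, test, bootstrap_reps=200, seed=0)
        row = report.iloc[0]
        assert row["auroc_lo"] <= row["auroc"] <= row["auroc_hi"]
        assert row["ap_lo"] <= row["average_precision"] <= row["ap_hi"]
        assert 0 <= row["auroc"] <= 1 and 0 <= row["average_precision"] <= 1

    def test_ci_width_shrinks_with_more_series(self):
        instances = toy_instances(160, 25, signal=3.0, seed=2)
        plan = split_series(instances["series_id"].unique(), seed=0)
        trained = tune_and_train(instances, plan, budget=1, seed=0,
                                 search_space=FAST_SPACE)
        test = instances[instances["series_id"].isin(plan.test_ids)]
        ids = sorted(test["series_id"].unique())
        small = test[test["series_id"].isin(ids[:10])]
        wide = evaluate_by_group(trained, small, bootstrap_reps=300, seed=0)
        narrow = evaluate_by_group(trained, test, bootstrap_reps=300, seed=0)
        w_small = wide.iloc[0]["auroc_hi"] - wide.iloc[0]["auroc_lo"]
        w_big = narrow.iloc[0]["auroc_hi"] - narrow.iloc[0]["auroc_lo"]
        assert w_big < w_small

    def test_single_class_group_reported_unevaluable(self, trained_setup):
        trained, test = trained_setup
        negatives = test[test["label"] == 0].copy()
        negatives["group"] = "only_negatives"
        report = evaluate_by_group(
            trained, pd.concat([test, negatives], ignore_index=True),
            bootstrap_reps=10, seed=0,
        )
        row = report[report["group"] == "only_negatives"].iloc[0]
        assert row["evaluable"] == False  # noqa: E712
        assert np.isnan(row["auroc"])

    def test_deterministic_given_seed(self, trained_setup):
        trained, test = trained_setup
        a = evaluate_by_group(trained, test, bootstrap_reps=50, seed=3)
        b = evaluate_by_group(trained, test, bootstrap_reps=50, seed=3)
        pd.testing.assert_frame_equal(a, b)
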