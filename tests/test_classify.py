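"""Subject-wise CV machinery: fold plans, tuned models, metrics,
undersampling, and leakage protection."""

import numpy as np
import pandas as pd
import pytest

import hrvstress as hs
from hrvstress.classify import METRICS, make_model

from conftest import make_labeled_frame


class TestFoldAssignment:
    def test_partition_and_fold_sizes(self):
        pids = np.array([f"P{i}" for i in range(147)])
        groups = np.array(["MDD"] * 41 + ["PD"] * 47 + ["HC"] * 59)
        plan = hs.assign_subject_folds(pids, groups, k=10, seed=0)
        assert set(plan) == set(pids.tolist())
        sizes = pd.Series(list(plan.values())).value_counts()
        assert set(sizes.tolist()) <= {14, 15}
        # group proportions per fold within +/- 2 participants of even share
        df = pd.DataFrame({"pid": pids, "group": groups})
        df["fold"] = df["pid"].map(plan)
        for g, sub in df.groupby("group"):
            per_fold = sub["fold"].value_counts().reindex(range(10), fill_value=0)
            assert per_fold.max() - per_fold.min() <= 2

    def test_task_rows_share_fold_by_construction(self):
        ds = make_labeled_frame()
        plan = hs.assign_subject_folds(ds, k=4, seed=1)
        folds = ds["participant"].map(plan)
        for (_, _), sub in ds.groupby(["participant", "visit"]):
            assert sub["participant"].map(plan).nunique() == 1
        assert folds.notna().all()

    def test_fewer_participants_than_folds_rejected(self):
        with pytest.raises(hs.ConfigError):
            hs.assign_subject_folds(np.array(["a", "b"]), np.array(["HC", "HC"]), k=10)


def _separable(n=30, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n * 2, 2))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += np.where(y == 1, 2.0, -2.0)
    groups = np.repeat([f"P{i}" for i in range(n)], 2)
    return X, y, groups


class TestTunedModels:
    def test_rf_grid_choice_and_separable_accuracy(self):
        X, y, groups = _separable()
        m = hs.TunedRandomForest(random_state=0).fit(X[:40], y[:40], groups=groups[:40])
        assert m.best_params_ in (50, 100, 200)
        acc = (m.predict(X[40:]) == y[40:]).mean()
        assert acc > 0.95

    def test_rf_deterministic_given_seed(self):
        X, y, groups = _separable()
        m1 = hs.TunedRandomForest(random_state=7).fit(X, y, groups=groups)
        m2 = hs.TunedRandomForest(random_state=7).fit(X, y, groups=groups)
        assert m1.best_params_ == m2.best_params_
        assert np.array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_single_class_training_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(hs.InsufficientDataError):
            hs.TunedRandomForest().fit(X, np.zeros(10, dtype=int))

    def test_mlp_grid_enumerates_six_combinations(self):
        grid = hs.TunedMLP()._grid()
        assert len(grid) == 6
        assert {tuple(a) for a, _ in grid} == {(4, 8, 16), (4, 8, 16, 32)}
        assert sorted({lr for _, lr in grid}) == [1e-4, 1e-3, 1e-2]

    def test_mlp_probabilities_bounded_and_separable_accuracy(self):
        X, y, groups = _separable(n=40, seed=2)
        m = hs.TunedMLP(random_state=0).fit(X[:60], y[:60], groups=groups[:60])
        proba = m.predict_proba(X[60:])
        assert np.all((proba >= 0) & (proba <= 1))
        assert (m.predict(X[60:]) == y[60:]).mean() > 0.9

    def test_unknown_family_rejected(self):
        with pytest.raises(hs.ConfigError):
            make_model("svm")


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 0])
        out = hs.evaluate(y.astype(float), y, y)
        assert all(out["overall"][m] == 1.0 for m in METRICS)

    def test_confusion_arithmetic(self):
        # TP=3, FP=1, FN=1, TN=5
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        out = hs.evaluate(pred.astype(float), pred, labels)["overall"]
        assert out["precision"] == pytest.approx(0.75)
        assert out["recall"] == pytest.approx(0.75)
        assert out["f1"] == pytest.approx(0.75)
        assert out["accuracy"] == pytest.approx(0.8)

    def test_constant_probability_gives_chance_auc(self):
        labels = np.array([1, 0, 1, 0, 1, 0])
        out = hs.evaluate(np.full(6, 0.5), np.ones(6, dtype=int), labels)
        assert out["overall"]["auc"] == pytest.approx(0.5)

    def test_single_class_scope_auc_flagged(self):
        labels = np.array([1, 1, 1])
        out = hs.evaluate(np.array([0.9, 0.8, 0.7]), np.ones(3, dtype=int), labels)
        assert np.isnan(out["overall"]["auc"])

    def test_f1_consistent_with_precision_recall(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 50)
        pred = rng.integers(0, 2, 50)
        out = hs.evaluate(pred.astype(float), pred, labels)["overall"]
        p, r = out["precision"], out["recall"]
        expected = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        assert out["f1"] == pytest.approx(expected, abs=1e-9)


class TestUndersample:
    def _dataset(self, sessions=(181, 191, 278)):
        rows = []
        for g, n in zip(hs.GROUPS, sessions):
            for i in range(n):
                for task in ("stress", "relaxation"):
                    rows.append({"participant": f"{g}{i // 5}", "group": g,
                                 "visit": i % 5, "task": task, "mean_rri": 0.8})
        return pd.DataFrame(rows)

    def test_reduces_to_smallest_group_row_count(self):
        ds = self._dataset()
        out = hs.undersample(ds, seed=0)
        counts = out.groupby("group").size()
        assert counts.tolist() == [362, 362, 362]

    def test_balanced_input_unchanged_up_to_order(self):
        ds = self._dataset(sessions=(50, 50, 50))
        out = hs.undersample(ds, seed=1)
        assert len(out) == len(ds)

    def test_output_is_subset_preserving_pairs(self):
        ds = self._dataset(sessions=(20, 30, 40))
        out = hs.undersample(ds, seed=2)
        merged = out.merge(ds, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()
        pair_counts = out.groupby(["participant", "visit"]).size()
        assert set(pair_counts.tolist()) == {2}


class TestRepeatedCV:
    def test_planted_signal_high_accuracy_and_determinism(self):
        ds = make_labeled_frame(n_per_group=(4, 4, 4), effect=3.0, noise=0.3)
        cv1 = hs.repeated_cv(ds, model="rf", k=4, repeats=2,
                             scaling_mode="train-zscore", base_seed=0)
        cv2 = hs.repeated_cv(ds, model="rf", k=4, repeats=2,
                             scaling_mode="train-zscore", base_seed=0)
        assert cv1.metric("accuracy") > 0.9
        pd.testing.assert_frame_equal(cv1.per_repeat, cv2.per_repeat)
        # report carries per-group scopes alongside the overall one
        assert set(cv1.per_repeat["scope"]) == {"overall", "MDD", "PD", "HC"}

    def test_leakage_guard_passes_on_valid_plan(self):
        ds = make_labeled_frame()
        cv = hs.repeated_cv(ds, model="rf", k=3, repeats=1, scaling_mode="none",
                            base_seed=1)
        assert len(cv.per_repeat) > 0

    def test_invalid_scaling_mode_rejected(self):
        with pytest.raises(hs.ConfigError):
            hs.repeated_cv(make_labeled_frame(), scaling_mode="bogus")

    def test_summary_self_consistency(self):
        ds = make_labeled_frame(effect=1.0)
        cv = hs.repeated_cv(ds, model="rf", k=3, repeats=2,
                            scaling_mode="train-zscore", base_seed=3)
        s = cv.summary()
        assert set(s["metric"]) == set(METRICS)
        assert ((s["mean"] >= 0) & (s["mean"] <= 1)).all()
        assert (s["sd"] >= 0).all()


class TestPerGroupModels:
    def test_three_isolated_models(self):
        ds = make_labeled_frame(n_per_group=(6, 6, 6), n_visits=3,
                                effect=3.0, noise=0.3)
        out = hs.per_group_models(ds, model="rf", k=3, repeats=1,
                                  scaling_mode="train-zscore", base_seed=0)
        assert set(out) == {"MDD", "PD", "HC"}
        for g, cv in out.items():
            assert cv.scope_label == g
            assert cv.metric("accuracy", scope=g) > 0.8
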