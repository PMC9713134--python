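"""Subject-wise splitting, standardization hygiene and merged-AUROC scoring."""

import numpy as np
import pandas as pd
import pytest

import vestigait as vg
from vestigait.classify import InvalidCohortError, Scaler, UndefinedAUROCError


def _toy_dataset(n_per_class=5, trials=2, informative=True, seed=0,
                 n_features=6):
    """Participant-grouped dataset with an optional class signal."""
    rng = np.random.default_rng(seed)
    rows, y, groups, index = [], [], [], []
    for label, prefix in ((0, "H"), (1, "V")):
        for i in range(1, n_per_class + 1):
            pid = f"{prefix}{i:02d}"
            offset = rng.normal(0, 0.3)
            for k in range(trials):
                x = rng.normal(0, 1.0, n_features)
                if informative:
                    # perfectly separable marker with participant jitter that
                    # never crosses the class boundary
                    x[0] = label * 3.0 + offset + rng.normal(0, 0.05)
                    x[1] = x[0] + rng.normal(0, 0.05)
                rows.append(x)
                y.append(label)
                groups.append(pid)
                index.append((pid, k))
    X = pd.DataFrame(np.vstack(rows),
                     index=pd.MultiIndex.from_tuples(
                         index, names=["participant_id", "trial_index"]))
    X.columns = [f"f{j}" for j in range(n_features)]
    return vg.features.TaskDataset("TOY", X, np.array(y), np.array(groups, object))


class TestSplitPlan:
    def test_sizes_and_no_overlap(self):
        participants = [f"H{i}" for i in range(15)] + [f"V{i}" for i in range(15)]
        labels = np.array([0] * 15 + [1] * 15)
        plan = vg.make_split_plan(participants, labels, n_repeats=50, seed=4)
        assert plan.n_repeats == 50
        for train, test in plan.repeats:
            assert len(train) == 24 and len(test) == 6
            assert not set(train) & set(test)
            assert sum(p.startswith("V") for p in test) == 3

    def test_deterministic(self):
        participants = [f"P{i}" for i in range(8)]
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        a = vg.make_split_plan(participants, labels, n_repeats=5, seed=9)
        b = vg.make_split_plan(participants, labels, n_repeats=5, seed=9)
        assert a == b

    def test_too_small_class_rejected(self):
        with pytest.raises(InvalidCohortError):
            vg.make_split_plan(["a", "b", "c", "d"], np.array([0, 0, 1, 1]))


class TestStandardize:
    def test_hand_computed(self):
        train = np.array([[1.0], [2.0], [3.0]])
        test = np.array([[2.0]])
        tr, te, _ = vg.standardize(train, test)
        np.testing.assert_allclose(tr[:, 0], [-1.22474487, 0.0, 1.22474487])
        assert te[0, 0] == 0.0  # test value equal to the train mean

    def test_constant_column_zeroed(self):
        train = np.full((4, 2), 7.0)
        train[:, 1] = [0, 1, 2, 3]
        test = np.array([[9.0, 1.5]])
        tr, te, scaler = vg.standardize(train, test)
        assert (tr[:, 0] == 0).all() and te[0, 0] == 0.0
        assert scaler.zero_variance.tolist() == [True, False]

    def test_fit_on_train_only(self, rng):
        train = rng.normal(size=(20, 3))
        test = rng.normal(size=(5, 3))
        _, _, scaler = vg.standardize(train, test)
        _, _, scaler2 = vg.standardize(train, test + 100.0)
        np.testing.assert_array_equal(scaler.mean, scaler2.mean)
        np.testing.assert_array_equal(scaler.std, scaler2.std)


class TestTuneAndTrain:
    def test_singleton_grid_skips_cv(self):
        ds = _toy_dataset()
        cfg = vg.ModelConfig.singleton(n_estimators=20)
        model, params, score = vg.tune_and_train(
            ds.X.to_numpy(), ds.y, ds.groups, cfg)
        assert params["n_estimators"] == 20
        assert np.isnan(score)

    def test_separable_features_score_one(self):
        ds = _toy_dataset(n_per_class=6, informative=True, seed=3)
        cfg = vg.ModelConfig(param_grid={"n_estimators": (20, 40),
                                         "max_depth": (None,)},
                             inner_cv_folds=3, seed=1)
        _, _, score = vg.tune_and_train(ds.X.to_numpy(), ds.y, ds.groups, cfg)
        assert score == 1.0

    def test_permuted_labels_near_chance(self):
        ds = _toy_dataset(n_per_class=8, trials=3, informative=False, seed=5)
        cfg = vg.ModelConfig(param_grid={"n_estimators": (30,),
                                         "max_depth": (None, 3)},
                             inner_cv_folds=4, seed=2)
        _, _, score = vg.tune_and_train(ds.X.to_numpy(), ds.y, ds.groups, cfg)
        assert 0.3 <= score <= 0.7  # winner of a 2-point grid on pure noise


class TestEvaluate:
    def test_separable_dataset_perfect_pool(self):
        ds = _toy_dataset(n_per_class=5, informative=True, seed=7, n_features=2)
        labels = np.array([ds.participant_labels()[p] for p in ds.participants])
        plan = vg.make_split_plan(ds.participants, labels, n_repeats=8, seed=1)
        res = vg.evaluate(plan, ds, vg.ModelConfig.singleton(n_estimators=50,
                                                             seed=2))
        assert res.auroc == 1.0
        assert res.accuracy == 1.0
        assert res.confusion.sum() == len(res.predictions)
        lo, hi = res.auroc_ci
        assert lo <= res.auroc <= hi

    def test_null_dataset_near_chance(self):
        # small subject-wise splits are slightly pessimistic on pure noise,
        # so use a cohort large enough for the pool to settle near 0.5
        ds = _toy_dataset(n_per_class=10, trials=3, informative=False, seed=11)
        labels = np.array([ds.participant_labels()[p] for p in ds.participants])
        plan = vg.make_split_plan(ds.participants, labels, n_repeats=30, seed=3)
        res = vg.evaluate(plan, ds, vg.ModelConfig.singleton(n_estimators=50,
                                                             seed=4))
        assert 0.35 <= res.auroc <= 0.65

    def test_predictions_only_from_holdout(self):
        ds = _toy_dataset(n_per_class=5, seed=13)
        labels = np.array([ds.participant_labels()[p] for p in ds.participants])
        plan = vg.make_split_plan(ds.participants, labels, n_repeats=6, seed=5)
        res = vg.evaluate(plan, ds, vg.ModelConfig.singleton(n_estimators=10))
        for (train, test), (_, grp) in zip(
                plan.repeats, res.predictions.groupby("repeat")):
            assert set(grp["participant_id"]) <= set(test)
            assert not set(grp["participant_id"]) & set(train)


class TestPlacementTaskGrid:
    def test_single_cell_and_margins(self):
        cfg = vg.SimConfig(n_per_class=4, tasks=("GEC",), trials_per_task=2,
                           placements=("l_arm",), seed=17)
        trials, _ = vg.simulate_cohort(cfg)
        ds = vg.build_dataset(trials, "GEC", vg.FeatureSpec(("l_arm",)))
        matrix, results = vg.placement_task_grid(
            {"GEC": ds}, ["l_arm"], vg.ModelConfig.singleton(n_estimators=30),
            n_repeats=4, split_seed=2)
        assert ("l_arm", "GEC") in results
        assert matrix.loc["l_arm", "GEC"] == results[("l_arm", "GEC")].auroc
        assert matrix.loc["l_arm", "mean"] == matrix.loc["l_arm", "GEC"]
        assert matrix.loc["mean", "GEC"] == matrix.loc["l_arm", "GEC"]


def test_dose_response_of_class_contrast():
    """Widening the between-class arm-swing gap never lowers the merged
    AUROC of the left-arm eyes-closed model (3-point dose check)."""
    aurocs = []
    for vest_mean in (0.49, 0.375, 0.26):  # no gap -> full gap
        cfg = vg.SimConfig(n_per_class=8, tasks=("GEC",), trials_per_task=3,
                           placements=("l_arm",),
                           arm_pitch_range=(0.49, vest_mean), seed=23)
        trials, _ = vg.simulate_cohort(cfg)
        ds = vg.build_dataset(trials, "GEC", vg.FeatureSpec(("l_arm",)))
        labels = np.array([ds.participant_labels()[p] for p in ds.participants])
        plan = vg.make_split_plan(ds.participants, labels, n_repeats=15, seed=31)
        res = vg.evaluate(plan, ds, vg.ModelConfig.singleton(n_estimators=100,
                                                             seed=37))
        aurocs.append(res.auroc)
    assert aurocs[0] <= aurocs[1] <= aurocs[2]
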