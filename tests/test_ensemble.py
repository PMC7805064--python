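import math

import numpy as np
import pandas as pd
import pytest

from dilipred.datatypes import DiliClass, DrugRecord, FeatureMatrix
from dilipred.ensemble import (
    SplitPlan,
    make_split,
    predict_holdout,
    round_half_away,
    stack,
    tune_and_fit,
)


def cohort(n_most, n_less, n_no):
    drugs = [DrugRecord(f"m{i}", DiliClass.MOST) for i in range(n_most)]
    drugs += [DrugRecord(f"l{i}", DiliClass.LESS) for i in range(n_less)]
    drugs += [DrugRecord(f"n{i}", DiliClass.NO) for i in range(n_no)]
    return drugs


def strata(ids):
    return (
        sum(d.startswith("m") for d in ids),
        sum(d.startswith("l") for d in ids),
        sum(d.startswith("n") for d in ids),
    )


class TestMakeSplit:
    def test_study_cohort_arithmetic(self):
        # 37/87/51 must give test 4+11+15, pool 109 DILI + 36 No-DILI,
        # and subsets of 11 Most + 25 Less + the common 36 No-DILI
        plan = make_split(cohort(37, 87, 51), seed=0)
        assert strata(plan.test_ids) == (4, 11, 15)
        pm, pl, pn = strata(plan.pool_ids)
        assert (pm + pl, pn) == (109, 36)
        assert len(plan.subsets) == 10
        common_no = None
        for sub in plan.subsets:
            assert strata(sub) == (11, 25, 36)
            no_set = frozenset(d for d in sub if d.startswith("n"))
            common_no = common_no or no_set
            assert no_set == common_no  # identical No-DILI drugs everywhere
        assert plan.r_most == pytest.approx(37 / 124)

    def test_symmetric_classes_give_symmetric_test(self):
        # equal Most/Less prevalence and an even test draw split evenly
        plan = make_split(cohort(20, 20, 40), test_fraction=0.5, seed=1)
        m, l, n = strata(plan.test_ids)
        assert m == l == 10 and n == 20

    def test_invariants_and_arithmetic_on_random_cohorts(self):
        rng = np.random.default_rng(2)
        checked = 0
        for _ in range(100):
            n_most = int(rng.integers(4, 40))
            n_less = int(rng.integers(4, 90))
            n_no = int(rng.integers(10, 60))
            r = n_most / (n_most + n_less)
            n_test_no = math.floor(0.30 * n_no)
            n_test_most = round_half_away(r * n_test_no)
            n_sub_most = round_half_away(r * (n_no - n_test_no))
            feasible = (
                n_test_most <= n_most
                and n_test_no - n_test_most <= n_less
                and n_sub_most <= n_most - n_test_most
                and (n_no - n_test_no) - n_sub_most <= n_less - (n_test_no - n_test_most)
            )
            if not feasible:
                with pytest.raises(ValueError):
                    make_split(cohort(n_most, n_less, n_no), seed=3)
                continue
            plan = make_split(cohort(n_most, n_less, n_no), seed=3)
            labels = {d.drug_id: d.dili_class for d in cohort(n_most, n_less, n_no)}
            plan.validate(labels)
            assert strata(plan.test_ids) == (
                n_test_most, n_test_no - n_test_most, n_test_no
            )
            for sub in plan.subsets:
                assert strata(sub) == (
                    n_sub_most, (n_no - n_test_no) - n_sub_most, n_no - n_test_no
                )
            checked += 1
        assert checked > 30  # most random cohorts must be feasible

    def test_seed_determinism(self):
        a = make_split(cohort(37, 87, 51), seed=5)
        b = make_split(cohort(37, 87, 51), seed=5)
        assert a.test_ids == b.test_ids and a.subsets == b.subsets

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            make_split(cohort(5, 5, 0))


def feature_matrix(ids, rng, informative_labels=None, noise=0.05):
    """Features whose first column encodes the label (plus noise) if given."""
    X = rng.normal(size=(len(ids), 5))
    if informative_labels is not None:
        X[:, 0] = [informative_labels[d] + noise * rng.normal() for d in ids]
    frame = pd.DataFrame(X, index=ids, columns=[f"f{j}" for j in range(5)])
    return FeatureMatrix(frame, {f"f{j}": "expression" for j in range(5)})


class TestTuneAndFit:
    ids = [f"d{i}" for i in range(40)]
    labels = {d: i % 2 == 0 for i, d in enumerate(ids)}

    def test_separable_subset_reaches_high_cv_accuracy(self):
        rng = np.random.default_rng(0)
        fm = feature_matrix(self.ids, rng, self.labels)
        model, params = tune_and_fit(fm, self.ids, self.labels, seed=0)
        assert params["cv_accuracy"] >= 0.95

    def test_constant_features_give_chance_accuracy(self):
        fm = FeatureMatrix(
            pd.DataFrame(0.0, index=self.ids, columns=["f0"]), {"f0": "expression"}
        )
        model, params = tune_and_fit(fm, self.ids, self.labels, seed=0)
        assert 0.2 <= params["cv_accuracy"] <= 0.8

    def test_same_seed_same_hyperparameters(self):
        rng = np.random.default_rng(1)
        fm = feature_matrix(self.ids, rng)
        _, p1 = tune_and_fit(fm, self.ids, self.labels, seed=4)
        _, p2 = tune_and_fit(fm, self.ids, self.labels, seed=4)
        assert p1 == p2

    def test_gradient_boosting_path(self):
        rng = np.random.default_rng(2)
        fm = feature_matrix(self.ids, rng, self.labels)
        model, params = tune_and_fit(
            fm, self.ids, self.labels, algorithm="gradient_boosting", seed=0
        )
        assert params["cv_accuracy"] >= 0.9
        assert {"n_estimators", "max_depth"} <= set(params)

    def test_unknown_algorithm(self):
        rng = np.random.default_rng(3)
        fm = feature_matrix(self.ids, rng)
        with pytest.raises(ValueError):
            tune_and_fit(fm, self.ids, self.labels, algorithm="svm")


class OracleModel:
    """Stand-in fitted base model: P(DILI) = clipped first feature."""

    classes_ = np.array([0, 1])

    def __init__(self, flip=False):
        self.flip = flip

    def predict_proba(self, X):
        p = np.clip(X[:, 0], 0.0, 1.0)
        if self.flip:
            p = 1.0 - p
        return np.column_stack([1.0 - p, p])


def exact_features(ids, labels):
    frame = pd.DataFrame(
        {"f0": [1.0 if labels[d] else 0.0 for d in ids]}, index=ids
    )
    return FeatureMatrix(frame, {"f0": "expression"})


class TestStacking:
    train_ids = [f"t{i}" for i in range(20)]
    test_ids = [f"x{i}" for i in range(16)]
    hold_ids = [f"h{i}" for i in range(12)]

    def plan(self):
        return SplitPlan(self.test_ids, self.train_ids, [self.train_ids] * 10, 0.3, 0)

    def all_labels(self):
        return {d: i % 2 == 0 for i, d in enumerate(self.train_ids + self.test_ids + self.hold_ids)}

    def test_consistent_committee_reproduces_labels(self):
        labels = self.all_labels()
        fm = exact_features(self.train_ids + self.test_ids + self.hold_ids, labels)
        model = stack([OracleModel() for _ in range(10)], fm, self.test_ids, labels, self.plan())
        pred = predict_holdout(model, fm, self.test_ids)
        assert all(pred.loc[d, "call"] == labels[d] for d in self.test_ids)

    def test_majority_beats_single_flipped_model(self):
        labels = self.all_labels()
        fm = exact_features(self.train_ids + self.test_ids + self.hold_ids, labels)
        models = [OracleModel() for _ in range(9)] + [OracleModel(flip=True)]
        ensemble = stack(models, fm, self.test_ids, labels, self.plan())
        pred = predict_holdout(ensemble, fm, self.hold_ids)
        stacked_acc = np.mean([pred.loc[d, "call"] == labels[d] for d in self.hold_ids])
        X = fm.values.loc[self.hold_ids].to_numpy()
        base_accs = [
            np.mean((m.predict_proba(X)[:, 1] >= 0.5) == [labels[d] for d in self.hold_ids])
            for m in models
        ]
        assert stacked_acc >= max(base_accs)

    def test_unfitted_base_model_rejected(self):
        labels = self.all_labels()
        fm = exact_features(self.train_ids + self.test_ids, labels)

        class Unfitted:
            pass

        with pytest.raises(ValueError):
            stack([Unfitted()], fm, self.test_ids, labels, self.plan())

    def test_test_train_overlap_rejected(self):
        labels = self.all_labels()
        fm = exact_features(self.train_ids + self.test_ids, labels)
        bad_plan = SplitPlan(
            self.test_ids, self.train_ids, [self.train_ids + self.test_ids[:1]], 0.3, 0
        )
        with pytest.raises(ValueError, match="training subsets"):
            stack([OracleModel()], fm, self.test_ids, labels, bad_plan)

    def test_empty_holdout_gives_empty_frame(self):
        labels = self.all_labels()
        fm = exact_features(self.train_ids + self.test_ids, labels)
        model = stack([OracleModel() for _ in range(10)], fm, self.test_ids, labels, self.plan())
        assert predict_holdout(model, fm, []).empty

    def test_feature_column_mismatch_rejected(self):
        labels = self.all_labels()
        fm = exact_features(self.train_ids + self.test_ids, labels)
        model = stack([OracleModel() for _ in range(10)], fm, self.test_ids, labels, self.plan())
        other = FeatureMatrix(
            pd.DataFrame({"other": [0.0]}, index=["h0"]), {"other": "expression"}
        )
        with pytest.raises(ValueError, match="feature columns"):
            predict_holdout(model, other, ["h0"])


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(4.47, 4), (4.5, 5), (10.74, 11), (0.5, 1), (-0.5, -1), (2.0, 2)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value) == expected
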