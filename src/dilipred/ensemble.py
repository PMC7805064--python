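"""Balanced split, 10 balanced training subsets, CV tuning and stacking.

The procedure, given n_most Most-, n_less Less- and n_no No-DILI-concern
drugs (e.g. 37/87/51):

1. draw floor(0.30 · n_no) No-DILI drugs for the test set (15), plus the
   same number of DILI drugs split by the Most/Less prevalence ratio
   r = n_most / (n_most + n_less) = 29.8%: round(r·15) = 4 Most and 11 Less;
2. the remaining drugs (109 DILI + 36 No-DILI) form the training pool;
   each of 10 training subsets reuses the identical 36 No-DILI drugs and
   draws round(r·36) = 11 Most and 25 Less uniformly at random without
   replacement from the pool, so every subset is balanced (36 vs 36) while
   jointly covering most DILI drugs;
3. each subset trains one base classifier, tuned by stratified 10-fold CV
   mean accuracy over a small explicit hyperparameter grid;
4. the 10 base models' positive-class probabilities on the test set become
   meta-features for a random-forest stacking classifier, which is the
   model applied to the independent hold-out drugs.

Note the meta-classifier is deliberately fitted on the same test set used
to report base-model metrics; its own metrics are therefore only honest on
held-out data, never by resubstitution on the test set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .datatypes import DiliClass, DrugRecord, FeatureMatrix

logger = logging.getLogger(__name__)


def round_half_away(x: float) -> int:
    """round() with half-away-from-zero ties, as in everyday arithmetic."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class SplitPlan:
    test_ids: list[str]
    pool_ids: list[str]
    subsets: list[list[str]]
    r_most: float
    seed: int

    def validate(self, labels: dict[str, DiliClass]) -> None:
        assert not set(self.test_ids) & set(self.pool_ids), "test/pool overlap"
        pool = set(self.pool_ids)
        for sub in self.subsets:
            assert set(sub) <= pool, "subset escapes the training pool"
            pos = sum(labels[d].is_positive for d in sub)
            assert pos * 2 == len(sub), "subset is not balanced"


@dataclass
class EnsembleModel:
    base_models: list
    base_params: list[dict]
    meta_model: object
    plan: SplitPlan
    feature_columns: list[str]
    algorithm: str


def make_split(
    drugs: list[DrugRecord],
    test_fraction: float = 0.30,
    n_subsets: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Build the balanced test set and the balanced training subsets.

    Rounding: floor for the No-DILI test draw; round-half-away-from-zero
    for the Most stratum, with Less as the complement — the unique simple
    rule reproducing the worked counts 15/4/11 and 11/25.
    """
    rng = np.random.default_rng(seed)
    most = sorted(d.drug_id for d in drugs if d.dili_class is DiliClass.MOST)
    less = sorted(d.drug_id for d in drugs if d.dili_class is DiliClass.LESS)
    no = sorted(d.drug_id for d in drugs if d.dili_class is DiliClass.NO)
    if not (most or less) or not no:
        raise ValueError("both DILI and No-DILI drugs are required")
    r = len(most) / (len(most) + len(less))

    n_test_no = math.floor(test_fraction * len(no))
    n_test_most = round_half_away(r * n_test_no)
    n_test_less = n_test_no - n_test_most
    for name, need, have in (
        ("Most-DILI", n_test_most, len(most)),
        ("Less-DILI", n_test_less, len(less)),
        ("No-DILI", n_test_no, len(no)),
    ):
        if need > have or need < 0:
            raise ValueError(f"stratum {name} exhausted: need {need}, have {have}")

    test_most = sorted(rng.choice(most, n_test_most, replace=False))
    test_less = sorted(rng.choice(less, n_test_less, replace=False))
    test_no = sorted(rng.choice(no, n_test_no, replace=False))
    test_ids = test_most + test_less + test_no

    pool_most = [d for d in most if d not in set(test_most)]
    pool_less = [d for d in less if d not in set(test_less)]
    pool_no = [d for d in no if d not in set(test_no)]
    pool_ids = pool_most + pool_less + pool_no

    n_train_no = len(pool_no)
    n_sub_most = round_half_away(r * n_train_no)
    n_sub_less = n_train_no - n_sub_most
    if n_sub_most > len(pool_most) or n_sub_less > len(pool_less):
        raise ValueError("DILI training pool exhausted for balanced subsets")

    subsets = []
    for i in range(n_subsets):
        sub_rng = np.random.default_rng(seed + i + 1)
        sm = sorted(sub_rng.choice(pool_most, n_sub_most, replace=False))
        sl = sorted(sub_rng.choice(pool_less, n_sub_less, replace=False))
        subsets.append(sm + sl + pool_no)
    return SplitPlan(test_ids, pool_ids, subsets, r, seed)


# ---------------------------------------------------------------------------
# Hyperparameter grids (small and explicit; complexity-ordered)

#: forest size for base classifiers; on ~70-drug balanced subsets CV accuracy
#: saturates well below this, so larger forests only add runtime
RF_TREES = 100


def _grid(algorithm: str, n_features: int) -> list[dict]:
    if algorithm == "random_forest":
        opts = sorted({max(1, round(math.sqrt(n_features))),
                       max(1, n_features // 4), max(1, n_features // 2)})
        return [{"n_estimators": RF_TREES, "max_features": m} for m in opts]
    if algorithm == "gradient_boosting":
        return [
            {"n_estimators": n, "max_depth": d, "learning_rate": 0.1,
             "min_samples_leaf": 10}
            for d in (1, 2, 3) for n in (100, 300)
        ]
    raise ValueError(f"unknown algorithm: {algorithm!r}")


def _make_model(algorithm: str, params: dict, seed: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    return GradientBoostingClassifier(random_state=seed, **params)


def tune_and_fit(
    features: FeatureMatrix,
    subset_ids: list[str],
    labels: dict[str, bool],
    algorithm: str = "random_forest",
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[object, dict]:
    """Grid search by stratified k-fold CV mean accuracy, then refit.

    Ties break toward lower model complexity (the grid is complexity
    ordered and only strictly better scores displace the incumbent).
    """
    X = features.values.loc[subset_ids].to_numpy(dtype=float)
    y = np.array([labels[d] for d in subset_ids], dtype=int)
    min_class = min(int(y.sum()), int((1 - y).sum()))
    folds = min(cv_folds, min_class)
    if folds < cv_folds:
        logger.warning("reducing CV folds from %d to %d (smallest class)", cv_folds, folds)
    if folds < 2:
        raise ValueError("subset too small for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    best_score, best_params = -np.inf, None
    for params in _grid(algorithm, X.shape[1]):
        accs = []
        for tr, te in splits:
            model = _make_model(algorithm, params, seed)
            model.fit(X[tr], y[tr])
            accs.append(float((model.predict(X[te]) == y[te]).mean()))
        score = float(np.mean(accs))
        if score > best_score:
            best_score, best_params = score, params
    final = _make_model(algorithm, best_params, seed)
    final.fit(X, y)
    return final, {**best_params, "cv_accuracy": best_score}


def base_probabilities(
    models: list, features: FeatureMatrix, ids: list[str]
) -> pd.DataFrame:
    """ids × models matrix of positive-class probabilities."""
    X = features.values.loc[ids].to_numpy(dtype=float)
    cols = {}
    for i, m in enumerate(models):
        pos = list(m.classes_).index(1)
        cols[f"base_{i + 1:02d}"] = m.predict_proba(X)[:, pos]
    return pd.DataFrame(cols, index=ids)


def stack(
    base_models: list,
    features: FeatureMatrix,
    test_ids: list[str],
    labels: dict[str, bool],
    plan: SplitPlan,
    algorithm: str = "random_forest",
    seed: int = 0,
) -> EnsembleModel:
    """Fit the random-forest meta-classifier on test-set base probabilities."""
    for m in base_models:
        if not hasattr(m, "classes_"):
            raise ValueError("all base models must be fitted before stacking")
    train_union = set().union(*map(set, plan.subsets)) if plan.subsets else set()
    leaked = set(test_ids) & train_union
    if leaked:
        raise ValueError(f"test drugs appear in training subsets: {sorted(leaked)}")
    meta_X = base_probabilities(base_models, features, test_ids)
    meta_y = np.array([labels[d] for d in test_ids], dtype=int)
    meta = RandomForestClassifier(n_estimators=RF_TREES, random_state=seed)
    meta.fit(meta_X.to_numpy(), meta_y)
    return EnsembleModel(
        base_models=base_models,
        base_params=[],
        meta_model=meta,
        plan=plan,
        feature_columns=list(features.values.columns),
        algorithm=algorithm,
    )


def predict_holdout(
    model: EnsembleModel, features: FeatureMatrix, holdout_ids: list[str]
) -> pd.DataFrame:
    """Per-drug stacked DILI probability and 0.5-threshold call."""
    if list(features.values.columns) != model.feature_columns:
        raise ValueError(
            "feature columns differ from training: "
            f"{list(features.values.columns)[:5]}... vs {model.feature_columns[:5]}..."
        )
    if not holdout_ids:
        return pd.DataFrame(columns=["probability", "call"])
    meta_X = base_probabilities(model.base_models, features, holdout_ids)
    pos = list(model.meta_model.classes_).index(1)
    prob = model.meta_model.predict_proba(meta_X.to_numpy())[:, pos]
    return pd.DataFrame(
        {"probability": prob, "call": prob >= 0.5}, index=holdout_ids
    )
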