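"""Binary drug × target feature block.

Validated and predicted drug-target associations are merged without
distinction. Drugs with no known targets cannot be represented in this
block and are excluded from training and testing when the target block is
in use; they are returned explicitly so callers can report them.
"""

from __future__ import annotations

import logging

import pandas as pd

from .datatypes import DiliClass, DrugRecord, FeatureMatrix

logger = logging.getLogger(__name__)


def build_target_matrix(
    targets: dict[str, frozenset[str]], cohort_ids: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """0/1 matrix over cohort drugs with >=1 target, plus excluded drug ids.

    The column universe is the union of targets observed over the included
    drugs; rows are binary membership indicators.
    """
    excluded = [d for d in cohort_ids if len(targets.get(d, frozenset())) == 0]
    included = [d for d in cohort_ids if d not in set(excluded)]
    universe = sorted(set().union(*(targets[d] for d in included)) if included else set())
    rows = {
        d: [1 if t in targets[d] else 0 for t in universe] for d in included
    }
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=universe).astype(int)
    if excluded:
        logger.warning("%d drugs excluded for empty target sets: %s", len(excluded), excluded)
    return mat, excluded


def target_block(mat: pd.DataFrame, target_universe: list[str] | None = None) -> FeatureMatrix:
    """Wrap a target matrix as a feature block, tagged "target".

    When ``target_universe`` is given (the training-time universe), novel
    columns are dropped with a warning and missing ones filled with 0.
    """
    if target_universe is not None:
        novel = [c for c in mat.columns if c not in set(target_universe)]
        if novel:
            logger.warning("dropping %d targets unseen at training time: %s", len(novel), novel)
        mat = mat.reindex(columns=target_universe, fill_value=0)
    cols = {f"tgt_{t}": "target" for t in mat.columns}
    block = mat.copy()
    block.columns = list(cols)
    return FeatureMatrix(block.astype(float), cols)


def target_class_profile(
    mat: pd.DataFrame, drugs: list[DrugRecord]
) -> pd.DataFrame:
    """Per-target fractions of DILI / No-DILI / hold-out drugs hitting it."""
    cls = {d.drug_id: d.dili_class for d in drugs}
    unknown = [d for d in mat.index if d not in cls]
    if unknown:
        raise KeyError(f"labels missing for drugs: {unknown}")
    groups = {
        "dili_fraction": [d for d in mat.index if cls[d].is_positive],
        "no_dili_fraction": [d for d in mat.index if cls[d] is DiliClass.NO],
        "holdout_fraction": [d for d in mat.index if cls[d] is DiliClass.AMBIGUOUS],
    }
    out = {}
    for name, ids in groups.items():
        out[name] = mat.loc[ids].mean(axis=0) if ids else pd.Series(0.0, index=mat.columns)
    prof = pd.DataFrame(out)
    prof.index.name = "target"
    return prof.sort_values("dili_fraction", ascending=False)
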