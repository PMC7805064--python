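"""End-to-end orchestration: inputs -> features -> split -> ensemble -> report.

A :class:`RunConfig` names the five inputs (or asks for a simulated
cohort), a feature recipe, the algorithm and the seeds; ``run_pipeline``
executes the full procedure deterministically and writes the model
artefacts, metric tables and provenance into a run directory.

Feature recipes (combinable with '+', columns concatenated without
rescaling — z-scores, similarities and binary target hits are already
bounded or standardised in their own terms):

* ``landmark``       — all measured genes as expression features
* ``wilcoxon``       — the rank-sum-selected gene signature
* ``phenotype:ID``   — one phenotype gene set's genes
* ``chem``           — Tanimoto similarities to the training-pool drugs
* ``target``         — binary drug-target hits (zero-target drugs excluded)
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .datatypes import DiliClass, DrugRecord, FeatureMatrix, GeneSignature
from .chem import chem_block, fingerprints_from_smiles, similarity_matrix
from .ensemble import make_split, predict_holdout, stack, tune_and_fit
from .evaluation import EvaluationReport, evaluate_model
from .expression import SampleFilter, collapse_to_drug, expression_block, select_samples
from .signatures import phenotype_signature, wilcoxon_signature
from .simulate import SimulationConfig, SyntheticCohort, simulate_cohort
from .targets import build_target_matrix, target_block

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    recipe: str = "wilcoxon"
    algorithm: str = "random_forest"
    alpha: float = 0.05
    sample_filter: SampleFilter = field(default_factory=SampleFilter)
    test_fraction: float = 0.30
    n_subsets: int = 10
    cv_folds: int = 10
    fp_length: int = 1024
    seed: int = 0
    permute_labels: bool = False  # null configuration: shuffle class labels
    # either a simulation config or paths to the five inputs
    simulation: SimulationConfig | None = None
    expression_path: str | None = None
    labels_path: str | None = None
    fingerprints_path: str | None = None
    smiles_path: str | None = None
    targets_path: str | None = None
    gene_sets_path: str | None = None


@dataclass
class RunResult:
    report: EvaluationReport
    holdout_predictions: pd.DataFrame
    holdout_metrics: dict | None
    model: object
    signature_size: int | None
    excluded_drugs: list[str]


def _load_inputs(cfg: RunConfig) -> SyntheticCohort:
    if cfg.simulation is not None:
        sim = cfg.simulation
        if sim.seed != cfg.seed:
            sim = SimulationConfig(**{**asdict(sim), "seed": cfg.seed})
        return simulate_cohort(sim)
    drugs = dio.read_gold_standard(cfg.labels_path)
    samples = dio.read_expression_table(cfg.expression_path)
    gene_sets = dio.read_gene_sets(cfg.gene_sets_path) if cfg.gene_sets_path else []
    if cfg.fingerprints_path:
        fps = dio.read_fingerprints(cfg.fingerprints_path)
    elif cfg.smiles_path:
        fps = fingerprints_from_smiles(dio.read_smiles(cfg.smiles_path), cfg.fp_length)
    else:
        fps = {}
    targets = dio.read_targets(cfg.targets_path) if cfg.targets_path else {}
    return SyntheticCohort(drugs, samples, gene_sets, fps, targets, truth=None)


def feature_exclusions(cohort: SyntheticCohort, recipe: str) -> list[str]:
    """Drugs that cannot be represented under this recipe.

    Empty target sets (when the target block is used) and missing or
    unparsable fingerprints (when the chem block is used) exclude a drug
    from training, testing and hold-out prediction alike.
    """
    excluded: set[str] = set()
    parts = [p.strip() for p in recipe.split("+")]
    all_ids = [d.drug_id for d in cohort.drugs]
    if "target" in parts:
        excluded.update(
            d for d in all_ids if len(cohort.targets.get(d, frozenset())) == 0
        )
    if "chem" in parts:
        excluded.update(d for d in all_ids if d not in cohort.fingerprints)
    return sorted(excluded)


def assemble_features(
    cohort: SyntheticCohort, cfg: RunConfig, pool_ids: list[str]
) -> tuple[FeatureMatrix, int | None]:
    """Build the feature matrix for a recipe over all representable drugs.

    ``pool_ids`` is the training pool; chem similarity columns are
    restricted to it so no test or hold-out information enters a feature.
    Returns (features, signature size or None).
    """
    labels = {d.drug_id: d.dili_class for d in cohort.drugs}
    binary = {d: c.is_positive for d, c in labels.items() if c.is_labelled}

    drug_vectors = None
    signature_size = None
    blocks: list[FeatureMatrix] = []

    def vectors() -> pd.DataFrame:
        nonlocal drug_vectors
        if drug_vectors is None:
            kept = select_samples(cohort.samples, cfg.sample_filter)
            drug_vectors = collapse_to_drug(kept)
        return drug_vectors

    for part in cfg.recipe.split("+"):
        part = part.strip()
        if part == "landmark":
            vec = vectors()
            sig = GeneSignature(list(vec.columns), provenance="gene-set")
            blocks.append(expression_block(vec, sig))
        elif part == "wilcoxon":
            vec = vectors()
            sig, _ = wilcoxon_signature(vec, binary, alpha=cfg.alpha)
            signature_size = len(sig)
            blocks.append(expression_block(vec, sig))
        elif part.startswith("phenotype:"):
            vec = vectors()
            sig = phenotype_signature(cohort.gene_sets, part.split(":", 1)[1], vec.columns)
            signature_size = len(sig)
            blocks.append(expression_block(vec, sig))
        elif part == "chem":
            sim = similarity_matrix(cohort.fingerprints)
            reference = [d for d in pool_ids if d in sim.index]
            blocks.append(chem_block(sim, reference))
        elif part == "target":
            mat, _ = build_target_matrix(cohort.targets, list(labels))
            blocks.append(target_block(mat))
        else:
            raise ValueError(f"unknown feature recipe component: {part!r}")

    features = blocks[0]
    for b in blocks[1:]:
        common = [d for d in features.drug_ids if d in set(b.drug_ids)]
        features = FeatureMatrix(features.values.loc[common], features.blocks).concat(
            FeatureMatrix(b.values.loc[common], b.blocks)
        )
    return features, signature_size


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full procedure; deterministic given the config seed."""
    cohort = _load_inputs(cfg)
    if cfg.permute_labels:
        rng = np.random.default_rng(cfg.seed)
        labelled_drugs = [d for d in cohort.drugs if d.dili_class.is_labelled]
        shuffled = [labelled_drugs[i].dili_class for i in rng.permutation(len(labelled_drugs))]
        for d, c in zip(labelled_drugs, shuffled):
            d.dili_class = c
    labels = {d.drug_id: d.dili_class for d in cohort.drugs}
    binary = {d: c.is_positive for d, c in labels.items() if c.is_labelled}

    excluded = feature_exclusions(cohort, cfg.recipe)
    labelled = [
        d for d in cohort.drugs
        if d.dili_class.is_labelled and d.drug_id not in set(excluded)
    ]
    plan = make_split(labelled, cfg.test_fraction, cfg.n_subsets, cfg.seed)
    features, signature_size = assemble_features(cohort, cfg, plan.pool_ids)
    usable = set(features.drug_ids)
    plan.validate(labels)

    base_models, base_params = [], []
    for i, subset in enumerate(plan.subsets):
        model, params = tune_and_fit(
            features, subset, binary, cfg.algorithm, cfg.cv_folds, seed=cfg.seed + i
        )
        base_models.append(model)
        base_params.append(params)

    report = EvaluationReport()
    from .ensemble import base_probabilities

    probs = base_probabilities(base_models, features, plan.test_ids)
    for col in probs.columns:
        _, m = evaluate_model(probs[col].to_dict(), binary)
        report.base_rows.append(m)

    model = stack(
        base_models, features, plan.test_ids, binary, plan, cfg.algorithm, cfg.seed
    )
    model.base_params = base_params

    holdout_ids = [
        d.drug_id
        for d in cohort.drugs
        if d.dili_class is DiliClass.AMBIGUOUS and d.drug_id in usable
    ]
    holdout_pred = predict_holdout(model, features, holdout_ids)

    holdout_metrics = None
    if cohort.truth is not None and holdout_ids:
        truth = cohort.truth.ambiguous_truth
        _, holdout_metrics = evaluate_model(
            holdout_pred["probability"].to_dict(), truth
        )
        report.stacked_row = holdout_metrics

    result = RunResult(report, holdout_pred, holdout_metrics, model, signature_size, excluded)
    if out_dir is not None:
        _write_run(Path(out_dir), cfg, plan, result)
    return result


def _write_run(out: Path, cfg: RunConfig, plan, result: RunResult) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_frame().to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.6f")
    result.holdout_predictions.to_csv(out / "holdout_predictions.tsv", sep="\t", float_format="%.6f")
    with open(out / "split_plan.json", "w") as fh:
        json.dump(
            {"test_ids": plan.test_ids, "pool_ids": plan.pool_ids,
             "subsets": plan.subsets, "r_most": plan.r_most, "seed": plan.seed},
            fh, indent=1,
        )
    cfg_dict = asdict(cfg)
    cfg_dict["sample_filter"] = asdict(cfg.sample_filter)
    prov = {
        "config": cfg_dict,
        "signature_size": result.signature_size,
        "excluded_drugs": result.excluded_drugs,
        "base_params": result.model.base_params,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=1, default=str)
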