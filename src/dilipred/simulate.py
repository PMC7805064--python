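"""Synthetic cohort generator.

Emulates the statistical structure of the challenge-style inputs the pipeline
consumes — a DILIrank-like label table, L1000-style moderated z-score
signatures over a condition grid, molecular fingerprints, drug-target edges
and phenotype gene sets — so every downstream stage is testable without any
external download.

Key structural choices:

* **Heterogeneous transcriptomic signal.** Each planted signal gene is
  shifted (by ``effect_size``, with a per-gene random sign) only in an
  independent random subset of the truly-DILI drugs (``perturb_fraction``),
  modelling the observation that signature genes respond in few compounds
  rather than uniformly across the positive class.
* **Hidden hold-out truth.** Ambiguous-concern drugs receive full data but a
  hidden binary truth label (drawn at the labelled DILI prevalence), stored
  only in the truth record, mirroring a hold-out set whose re-assigned
  labels are withheld.
* **Chemical heterogeneity.** No-DILI fingerprints are mutations of one
  shared template (higher within-class Tanimoto); DILI fingerprints come
  from a diffuse multi-template mixture (lower within-class Tanimoto).
* **Target enrichment.** A designated subset of targets is hit by DILI
  drugs with odds multiplied by ``target_enrichment`` over the baseline hit
  probability, emulating liver-enzyme targets over-represented among
  hepatotoxic drugs. A small configured set of drugs has no targets at all,
  to exercise the zero-target exclusion path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import DiliClass, DrugRecord, ExpressionSample, GeneSet


@dataclass
class SimulationConfig:
    # class sizes (defaults reproduce the study cohort proportions)
    n_most: int = 37
    n_less: int = 87
    n_no: int = 51
    n_ambiguous: int = 55
    # expression
    n_genes: int = 978
    n_signal_genes: int = 66
    effect_size: float = 1.5  # mean z-shift of a perturbed gene
    perturb_fraction: float = 0.3  # fraction of DILI drugs perturbing each signal gene
    cell_lines: tuple[str, ...] = ("PHH", "HEPG2")
    doses: tuple[float, ...] = (10.0,)
    times: tuple[float, ...] = (6.0, 24.0)
    n_replicates: int = 5  # level-5 signatures per drug-condition cell
    # chemistry: density/mutation calibrated so expected within-class mean
    # Tanimoto is ~0.24 for No-DILI (one shared template) and ~0.18 for
    # Most-DILI (8-template mixture), matching the reported class structure
    fp_length: int = 1024
    fp_density: float = 0.1  # template bit density
    no_dili_mutation: float = 0.30  # per-bit flip rate around the No-DILI template
    dili_mutation: float = 0.25
    n_dili_templates: int = 8  # mixture size for the diffuse DILI classes
    # targets
    n_targets: int = 200
    n_enriched_targets: int = 20
    target_base_prob: float = 0.05
    target_enrichment: float = 3.0
    n_zero_target_labelled: int = 3
    n_zero_target_ambiguous: int = 2
    # gene sets
    n_phenotypes: int = 9
    phenotype_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_most", "n_less", "n_no", "n_ambiguous", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes exceeds n_genes")
        if not 0 < self.perturb_fraction <= 1:
            raise ValueError("perturb_fraction must lie in (0, 1]")
        if self.fp_length < 64:
            raise ValueError("fp_length must be >= 64")
        if (10.0 not in self.doses) or ("PHH" not in self.cell_lines) or (
            not any(t >= 24 for t in self.times)
        ):
            raise ValueError("condition grid must include PHH / 10 uM / >=24 h")


@dataclass
class TruthRecord:
    """Ground truth of the planted structure, for evaluation only."""

    signal_genes: list[str]
    signal_signs: dict[str, int]
    enriched_targets: list[str]
    ambiguous_truth: dict[str, bool]  # drug_id -> truly DILI
    zero_target_drugs: list[str]
    config: dict = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    drugs: list[DrugRecord]
    samples: list[ExpressionSample]
    gene_sets: list[GeneSet]
    fingerprints: dict[str, np.ndarray]
    targets: dict[str, frozenset[str]]
    truth: TruthRecord


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def simulate_drugs(config: SimulationConfig, rng: np.random.Generator) -> list[DrugRecord]:
    labels = (
        [DiliClass.MOST] * config.n_most
        + [DiliClass.LESS] * config.n_less
        + [DiliClass.NO] * config.n_no
        + [DiliClass.AMBIGUOUS] * config.n_ambiguous
    )
    order = rng.permutation(len(labels))
    return [
        DrugRecord(f"D{i:04d}", labels[order[i]]) for i in range(len(labels))
    ]


def simulate_expression(
    config: SimulationConfig,
    drugs: list[DrugRecord],
    truly_dili: set[str],
    rng: np.random.Generator,
) -> tuple[list[ExpressionSample], list[str], dict[str, int]]:
    """Background N(0,1) z-scores with per-gene planted shifts.

    Returns the samples, the planted signal gene ids and their shift signs.
    """
    genes = _gene_ids(config.n_genes)
    gene_index = pd.Index(genes)
    signal_idx = rng.choice(config.n_genes, size=config.n_signal_genes, replace=False)
    signal_genes = sorted(genes[i] for i in signal_idx)
    signs = {g: int(s) for g, s in zip(signal_genes, rng.choice([-1, 1], len(signal_genes)))}

    drug_ids = [d.drug_id for d in drugs]
    drug_pos = {d: i for i, d in enumerate(drug_ids)}
    dili_ids = sorted(d for d in drug_ids if d in truly_dili)
    n_pert = max(1, round(config.perturb_fraction * len(dili_ids)))
    # per-gene independent subsets of perturbed drugs
    shift = np.zeros((len(drugs), config.n_genes))
    gene_pos = {g: j for j, g in enumerate(genes)}
    for g in signal_genes:
        chosen = rng.choice(dili_ids, size=n_pert, replace=False)
        rows = [drug_pos[d] for d in chosen]
        shift[rows, gene_pos[g]] = signs[g] * config.effect_size

    conditions = [
        (cl, dose, t)
        for cl in config.cell_lines
        for dose in config.doses
        for t in config.times
        for _ in range(config.n_replicates)
    ]
    n_samples = len(drugs) * len(conditions)
    noise = rng.normal(size=(n_samples, config.n_genes))

    samples: list[ExpressionSample] = []
    k = 0
    for i, d in enumerate(drugs):
        for cl, dose, t in conditions:
            samples.append(
                ExpressionSample(
                    sample_id=f"S{k:06d}",
                    drug_id=d.drug_id,
                    cell_line=cl,
                    dose=dose,
                    time=t,
                    zscores=pd.Series(noise[k] + shift[i], index=gene_index),
                )
            )
            k += 1
    return samples, signal_genes, signs


def simulate_fingerprints(
    config: SimulationConfig,
    drugs: list[DrugRecord],
    truly_dili: set[str],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Binary fingerprints with class-dependent structural coherence.

    Truly non-DILI drugs (including hidden-truth ambiguous ones) mutate a
    single shared template, so their within-class Tanimoto similarity is
    high; truly DILI drugs mix several templates at their own mutation
    rate, giving the lower within-class similarity observed for hepatotoxic
    compounds.
    """
    base = rng.random(config.fp_length) < config.fp_density
    dili_templates = [
        rng.random(config.fp_length) < config.fp_density
        for _ in range(config.n_dili_templates)
    ]
    fps = {}
    for d in drugs:
        if d.drug_id not in truly_dili:
            template, rate = base, config.no_dili_mutation
        else:
            template = dili_templates[rng.integers(config.n_dili_templates)]
            rate = config.dili_mutation
        flip = rng.random(config.fp_length) < rate
        fps[d.drug_id] = np.where(flip, ~template, template)
    return fps


def mutate_template(
    template: np.ndarray, mutation_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """One fingerprint drawn by flipping template bits at ``mutation_rate``."""
    flip = rng.random(len(template)) < mutation_rate
    return np.where(flip, ~template.astype(bool), template.astype(bool))


def simulate_targets(
    config: SimulationConfig,
    drugs: list[DrugRecord],
    truly_dili: set[str],
    rng: np.random.Generator,
) -> tuple[dict[str, frozenset[str]], list[str], list[str]]:
    """Bernoulli drug-target hits with DILI-enriched columns.

    Returns (drug -> target set, enriched target ids, zero-target drug ids).
    """
    target_ids = [f"T{i:03d}" for i in range(config.n_targets)]
    enriched = sorted(
        target_ids[i]
        for i in rng.choice(config.n_targets, config.n_enriched_targets, replace=False)
    )
    enriched_set = set(enriched)
    p0 = config.target_base_prob
    p1 = min(1.0, config.target_enrichment * p0)

    labelled = [d for d in drugs if d.dili_class.is_labelled]
    ambiguous = [d for d in drugs if not d.dili_class.is_labelled]
    zero_ids = [
        d.drug_id
        for d in list(rng.choice(labelled, config.n_zero_target_labelled, replace=False))
        + list(rng.choice(ambiguous, config.n_zero_target_ambiguous, replace=False))
    ]
    zero_set = set(zero_ids)

    out = {}
    for d in drugs:
        if d.drug_id in zero_set:
            out[d.drug_id] = frozenset()
            continue
        is_dili = d.drug_id in truly_dili
        hits = set()
        for t in target_ids:
            p = p1 if (is_dili and t in enriched_set) else p0
            if rng.random() < p:
                hits.add(t)
        if not hits:  # guarantee a non-empty row for non-designated drugs
            hits.add(target_ids[rng.integers(config.n_targets)])
        out[d.drug_id] = frozenset(hits)
    return out, enriched, zero_ids


def simulate_gene_sets(
    config: SimulationConfig, signal_genes: list[str], rng: np.random.Generator
) -> list[GeneSet]:
    """Phenotype gene sets, each mixing planted signal genes with background."""
    genes = _gene_ids(config.n_genes)
    sets = []
    for i in range(config.n_phenotypes):
        n_sig = min(len(signal_genes), max(1, config.phenotype_size // 3))
        sig = rng.choice(signal_genes, n_sig, replace=False)
        bg_pool = [g for g in genes if g not in set(sig)]
        bg = rng.choice(bg_pool, config.phenotype_size - n_sig, replace=False)
        sets.append(
            GeneSet(f"PH{i:02d}", f"synthetic liver phenotype {i}", frozenset(sig) | frozenset(bg))
        )
    return sets


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a complete cohort; byte-reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    drugs = simulate_drugs(config, rng)

    labelled_dili = {d.drug_id for d in drugs if d.dili_class.is_positive}
    labelled = [d for d in drugs if d.dili_class.is_labelled]
    prevalence = len(labelled_dili) / len(labelled)
    ambiguous_truth = {
        d.drug_id: bool(rng.random() < prevalence)
        for d in drugs
        if d.dili_class is DiliClass.AMBIGUOUS
    }
    truly_dili = labelled_dili | {d for d, v in ambiguous_truth.items() if v}

    samples, signal_genes, signs = simulate_expression(config, drugs, truly_dili, rng)
    fps = simulate_fingerprints(config, drugs, truly_dili, rng)
    targets, enriched, zero_ids = simulate_targets(config, drugs, truly_dili, rng)
    gene_sets = simulate_gene_sets(config, signal_genes, rng)

    for d in drugs:
        d.targets = targets[d.drug_id]

    truth = TruthRecord(
        signal_genes=signal_genes,
        signal_signs=signs,
        enriched_targets=enriched,
        ambiguous_truth=ambiguous_truth,
        zero_target_drugs=zero_ids,
        config=asdict(config),
    )
    return SyntheticCohort(drugs, samples, gene_sets, fps, targets, truth)
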