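# Methods

## Problem and scope

`dilipred` classifies drugs into DILI-concern (positive: Most- or
Less-DILI-Concern) vs No-DILI-Concern from transcriptomic, chemical and
drug-target features. Ambiguous-DILI-Concern drugs are never used for
training or testing; they form an independent hold-out set whose (hidden)
binary labels are known only to the synthetic-data generator, which uses
them to score hold-out predictions.

## Synthetic cohort generator

The generator (`dilipred.simulate`) emulates the statistical structure of a
DILIrank + L1000-style input bundle. Its defaults define the study conditions; each
component and the rationale for its free parameters:

**Cohort.** 37 Most / 87 Less / 51 No / 55 Ambiguous drugs (the printed
class sizes). Ambiguous drugs receive a hidden truth label drawn at the
labelled DILI prevalence (124/175 ≈ 0.71), reflecting that most ambiguous
drugs were eventually re-assigned to the DILI side.

**Expression.** Moderated z-scores are N(0, 1) background noise over 978
landmark genes, on a condition grid of {PHH, HEPG2} cell lines × 10 µM ×
{6, 24} h with 5 level-5 signature replicates per drug-condition cell
(emulating multiple independent signatures per condition, e.g. from
different plates). 66 signal genes are planted; each is shifted by the
effect size (default 1.5, with a fixed random sign per gene) in an
*independent* random subset of 30% of the truly-DILI drugs. The per-gene
(not per-drug) subsets model the observed heterogeneity of hepatotoxic
transcriptomic response: every signature gene responds in only a few
compounds, and no drug carries the whole signature.

The replicate count is the one free parameter with real statistical
leverage. After condition filtering and median collapse, a drug's per-gene
noise sd is ≈ 0.54 (median of 5 standard normals). Under the default
conditions the rank-sum screen (124 vs 51 drugs) then has ≈ 84% per-gene
power — with a single signature per condition the screen's power could not
exceed ~60% at a 30% perturbed fraction regardless of effect size, which
would contradict the recovery behaviour the pipeline is designed around.

**Chemistry.** Binary fingerprints are drawn by flipping bits of class
templates: No-DILI drugs mutate one shared template (rate 0.30), all
DILI-concern classes mutate one of 8 templates (rate 0.25), at template
density 0.1. These values are calibrated analytically so the expected
within-class mean Tanimoto is ≈ 0.24 for No-DILI and ≈ 0.18 for Most-DILI
drugs — the reported class structure: No-DILI drugs are chemically
coherent, DILI drugs structurally diverse.

**Targets.** 200 proteins, Bernoulli hits at base probability 0.05; on a
designated 20-target enriched subset, truly-DILI drugs hit with probability
3 × 0.05 (emulating liver-enzyme targets over-represented among hepatotoxic
drugs). Three labelled and two ambiguous drugs are generated with empty
target sets to exercise the zero-target exclusion path; every other drug is
guaranteed ≥ 1 target.

**Gene sets.** 9 phenotype sets of 30 genes, each mixing ~10 planted signal
genes with background genes, so phenotype-derived signatures are
informative but imperfect.

All outputs are byte-reproducible from the seed.

### What the generator does not emulate

Real L1000 data has gene-gene correlation, batch structure, dose-response
and replicate-quality variation; real chemistry has valid molecular
graphs (the generator emits fingerprints directly, though the pipeline
accepts SMILES via RDKit); real drug-target data is biased by research
attention. Passing tests therefore demonstrate that the *procedure* is
implemented correctly and recovers planted structure at realistic sizes and
noise levels — not that the reported real-data accuracies are reproduced,
which would require the original distribution.

## Sample selection and collapse

Condition filtering keeps samples with cell line exactly PHH, dose exactly
10 µM (tolerance 1e-9) and time ≥ 24 h — dose is filtered by equality, time
by bound. Per drug, samples at the longest available time are kept and
collapsed by per-gene median (the tie rule is ours; only "a single
dose-time point" is prescribed).

The alternative correlated-sample strategy ignores conditions: over one
drug's samples, all cross-cell-line pairs with Pearson r > 0.5 are
retained (else the single best pair), and the per-gene median over the
union of retained samples is the drug vector. Same-cell-line pairs are
deliberately not considered (literal reading of the cross-cell-line
consistency idea); pairs with an all-constant vector are skipped. Whether
the median should run over retained samples or over pair means is
ambiguous; we use the union of samples.

## Signature derivation

Per gene, a two-sided Wilcoxon rank-sum test compares collapsed z-scores of
DILI vs No-DILI drugs. The exact permutation null is used when the combined
sample size is ≤ 12 and tie-free; otherwise the normal approximation with
mid-rank tie correction and continuity correction. Genes with marginal
*p* strictly below α = 0.05 form the signature, sorted by ascending p with
lexicographic tie-break. No multiple-testing correction is applied — by
design the screen is a ranking device meant to capture broad signal, and
its false selections are accepted at the type-I rate. The signature is
derived from all labelled drugs (including the eventual test set), exactly
as in the original design; this is a known optimism source and is kept for
fidelity rather than "fixed".

## Feature blocks

* expression: one column per signature gene (collapsed z-scores);
* chem: one column per *training-pool* drug, holding Tanimoto similarity to
  it. Restricting reference columns to the pool keeps test/hold-out
  information out of the feature definition;
* target: one binary column per protein observed at training time; novel
  hold-out targets are dropped with a warning; drugs with empty target sets
  are excluded from training, testing and prediction when this block is in
  use.

Blocks combine by plain column concatenation without rescaling: z-scores,
similarities in [0,1] and binary hits are already bounded/standardised in
their own terms.

## Split and ensemble

With counts (n_most, n_less, n_no) and Most-prevalence r = n_most /
(n_most + n_less): the test set takes floor(0.30 · n_no) No-DILI drugs and
equally many DILI drugs, split round-half-away-from-zero(r · n) Most and
the complement Less. All remaining No-DILI drugs (the 70%) are shared by
every training subset; each of the 10 subsets draws round(r · n_train_no)
Most and the complement Less uniformly without replacement from the DILI
pool. This rounding scheme is the unique simple rule reproducing the
worked counts 15/4/11 and 36/11/25 at 37/87/51.

Base classifiers are tuned by stratified 10-fold CV mean accuracy over
small explicit grids — random forest: features-per-split ∈ {√p, p/4, p/2};
gradient boosting: trees ∈ {100, 300} × depth ∈ {1, 2, 3}, learning rate
0.1, min leaf 10 — with ties broken toward lower complexity, then refitted
on the full subset. Forests use 100 trees: on ~70-drug balanced subsets CV
accuracy is saturated well below that size, and larger forests only add
runtime. Folds shrink automatically (with a warning) if a class is smaller
than the fold count. Seeding: subset i uses seed + i; CV folds are seeded
from the subset seed.

The stacking meta-classifier (random forest, 100 trees) is trained on the
10 base models' positive-class probabilities for the *test* drugs against
the test labels — probabilities rather than hard calls, since they carry
confidence and degrade gracefully. Note the consequence: the meta-model is
fitted on the same test set used to report base-model metrics, exactly as
in the original design. Its own performance is therefore only reported on
the held-out ambiguous drugs (never by resubstitution on the test set,
which would be circular). Hold-out calls threshold the stacked probability
at 0.5.

## Evaluation

Confusion-based metrics (accuracy, precision, sensitivity, specificity,
F1, MCC) with the DILI class positive. Any metric with a zero denominator
is reported as 0 and flagged, so degenerate tables stay numeric. Reports
carry one row per base model, their arithmetic mean, and the stacked row.

## Numerical and degenerate-input conventions

* Tanimoto of two empty fingerprints is 0 (this also means a molecule with
  no bond paths, e.g. methane, has similarity 0 to everything including
  itself — a property of path-based fingerprints, not a bug);
* unparsable SMILES, empty target sets and unknown phenotype ids exclude a
  drug or raise, as documented per function; class tokens parse
  case-insensitively, any other token is a hard error;
* all randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical config + seed gives byte-identical
  artefacts.

## Problem sizes used in the test suite

Unit tests run on a reduced cohort (24 labelled + 5 ambiguous drugs, 40
genes) that preserves every structural feature of the full design.
Study-scale checks (978 genes, 230 drugs) run in `tests/test_acceptance.py`:
signature recovery uses 10 generator replicates; the end-to-end ensemble
check uses 5 seeds under strong signal (effect 3.0, 80% perturbed fraction)
and 3 seeds under label permutation — sizes chosen to give stable medians
while keeping the suite runnable on a laptop.

## Known limitations

The generator's independence assumptions (genes, drugs, targets) make the
synthetic task easier than the real one at equal effect sizes; real-data
accuracies are not expected to be reproduced. The meta-classifier's
test-set fitting inherits the original design's optimism. Fingerprints are
hashed path-based with configurable length; they are not bit-compatible
with any specific legacy fingerprint implementation, so similarity values
differ from any published matrix even for identical molecules.
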