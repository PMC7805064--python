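"""Gene-signature derivation.

Two routes produce a :class:`~dilipred.datatypes.GeneSignature`:

* a per-gene two-sided Wilcoxon rank-sum (Mann-Whitney) test of the drug
  collapsed z-scores between DILI-concern and No-DILI-concern drugs,
  keeping genes with marginal p < alpha (no multiple-testing correction —
  the intent is a ranking that captures the broad transcriptomic signal,
  not a strictly controlled discovery list);
* intersection of a curated phenotype gene set with the measured gene
  universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .datatypes import GeneSet, GeneSignature

logger = logging.getLogger(__name__)

#: combined sample size at or below which the exact null distribution is used
EXACT_N_MAX = 12


@dataclass
class GeneTestResult:
    gene_id: str
    statistic: float  # Mann-Whitney U of the first group
    p_value: float


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def wilcoxon_gene_test(x, y, gene_id: str = "") -> GeneTestResult:
    """Two-sided rank-sum test of one gene's z-scores, DILI vs No-DILI.

    Uses the exact permutation null when the combined sample size is at
    most ``EXACT_N_MAX`` and there are no ties, otherwise the normal
    approximation with mid-rank tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size + y.size <= EXACT_N_MAX and not _has_ties(x, y):
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GeneTestResult(gene_id, float(res.statistic), float(res.pvalue))


def wilcoxon_signature(
    drug_vectors: pd.DataFrame,
    labels: dict[str, bool],
    alpha: float = 0.05,
) -> tuple[GeneSignature, pd.DataFrame]:
    """Marginal per-gene rank-sum screen over a drugs × genes frame.

    ``labels`` maps drug id -> True for DILI; drugs absent from ``labels``
    are ignored. Genes with p strictly below ``alpha`` enter the signature,
    sorted by ascending p (ties broken lexicographically by gene id).
    Returns the signature and the full per-gene test table.
    """
    ids = [d for d in drug_vectors.index if d in labels]
    pos = [d for d in ids if labels[d]]
    neg = [d for d in ids if not labels[d]]
    if not pos or not neg:
        raise ValueError("both DILI and No-DILI drugs are required")
    x = drug_vectors.loc[pos].to_numpy()
    y = drug_vectors.loc[neg].to_numpy()

    if x.shape[0] + y.shape[0] <= EXACT_N_MAX:
        results = [
            wilcoxon_gene_test(x[:, j], y[:, j], g)
            for j, g in enumerate(drug_vectors.columns)
        ]
        stats = np.array([r.statistic for r in results])
        pvals = np.array([r.p_value for r in results])
    else:  # vectorised normal approximation across all genes at once
        res = mannwhitneyu(x, y, axis=0, alternative="two-sided", method="asymptotic")
        stats, pvals = np.asarray(res.statistic), np.asarray(res.pvalue)

    table = pd.DataFrame(
        {"gene_id": drug_vectors.columns, "statistic": stats, "p_value": pvals}
    )
    table["selected"] = table["p_value"] < alpha
    sel = table[table["selected"]].sort_values(["p_value", "gene_id"])
    signature = GeneSignature(
        genes=list(sel["gene_id"]),
        p_values=dict(zip(sel["gene_id"], sel["p_value"])),
        provenance="wilcoxon",
    )
    return signature, table


def phenotype_signature(
    gene_sets: list[GeneSet], phenotype_id: str, gene_universe
) -> GeneSignature:
    """Signature from a phenotype gene set, restricted to measured genes."""
    by_id = {gs.phenotype_id: gs for gs in gene_sets}
    if phenotype_id not in by_id:
        raise KeyError(f"unknown phenotype id: {phenotype_id!r}")
    gs = by_id[phenotype_id]
    universe = set(gene_universe)
    present = sorted(gs.genes & universe)
    missing = sorted(gs.genes - universe)
    if missing:
        logger.warning(
            "phenotype %s: %d genes not in expression universe: %s",
            phenotype_id, len(missing), missing,
        )
    if not present:
        raise ValueError(f"phenotype {phenotype_id!r} shares no genes with the universe")
    return GeneSignature(genes=present, provenance="gene-set")
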