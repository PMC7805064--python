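"""Sample selection and per-drug expression feature assembly.

Two selection strategies are provided:

* condition filtering — keep a liver-relevant condition (PHH cell line,
  10 µM, treatment >= 24 h) and collapse each drug's qualifying samples to
  one z-score vector (longest treatment, per-gene median over what remains);
* correlated-sample selection — ignore conditions and instead keep, per
  drug, the cross-cell-line sample pairs whose expression profiles agree
  (Pearson r above a threshold, falling back to the single best pair),
  then take the per-gene median over the retained samples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import ExpressionSample, FeatureMatrix, GeneSignature

logger = logging.getLogger(__name__)


@dataclass
class SampleFilter:
    """Condition filter; any unset field matches all samples."""

    cell_line: Optional[str] = "PHH"
    dose: Optional[float] = 10.0
    min_time: Optional[float] = 24.0

    def matches(self, s: ExpressionSample) -> bool:
        if self.cell_line is not None and s.cell_line != self.cell_line:
            return False
        if self.dose is not None and abs(s.dose - self.dose) > 1e-9:
            return False
        if self.min_time is not None and s.time < self.min_time:
            return False
        return True


def select_samples(
    samples: list[ExpressionSample], flt: SampleFilter
) -> list[ExpressionSample]:
    """Order-preserving subset of samples matching the filter."""
    kept = [s for s in samples if flt.matches(s)]
    if samples and not kept:
        logger.warning("sample filter %s removed all %d samples", flt, len(samples))
    return kept


def collapse_to_drug(samples: list[ExpressionSample]) -> pd.DataFrame:
    """Collapse filtered samples to one z-score vector per drug.

    Per drug: keep only samples at the longest available treatment time,
    then take the per-gene median if more than one remains. Returns a
    drugs × genes frame; drugs with no samples are simply absent.
    """
    by_drug: dict[str, list[ExpressionSample]] = {}
    for s in samples:
        by_drug.setdefault(s.drug_id, []).append(s)
    rows = {}
    for drug_id, ss in by_drug.items():
        tmax = max(s.time for s in ss)
        at_max = [s for s in ss if s.time == tmax]
        if len(at_max) == 1:
            rows[drug_id] = at_max[0].zscores
        else:
            rows[drug_id] = pd.concat([s.zscores for s in at_max], axis=1).median(axis=1)
    return pd.DataFrame(rows).T


def select_correlated_samples(
    samples: list[ExpressionSample], threshold: float = 0.5
) -> pd.Series:
    """Consistency-based selection over one drug's samples.

    Considers every pair of samples from *different* cell lines; retains all
    pairs with Pearson r > threshold, or, if none qualifies, the single most
    correlated pair. The result is the per-gene median over the union of
    retained samples. A lone sample is returned as-is. Pairs involving an
    all-constant vector (undefined correlation) are skipped.
    """
    if not samples:
        raise ValueError("select_correlated_samples requires >=1 sample")
    if len(samples) == 1:
        return samples[0].zscores.copy()

    pairs = []
    for a, b in itertools.combinations(samples, 2):
        if a.cell_line == b.cell_line:
            continue
        xa, xb = a.zscores.to_numpy(), b.zscores.to_numpy()
        if np.std(xa) == 0 or np.std(xb) == 0:
            logger.warning(
                "skipping pair (%s, %s): constant expression vector",
                a.sample_id, b.sample_id,
            )
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        pairs.append((r, a, b))

    if not pairs:
        # no valid cross-cell-line pair: fall back to all samples
        logger.warning("no valid cross-cell-line pair; using all %d samples", len(samples))
        retained = samples
    else:
        above = [(r, a, b) for r, a, b in pairs if r > threshold]
        if not above:
            above = [max(pairs, key=lambda t: t[0])]
        retained_ids: dict[str, ExpressionSample] = {}
        for _, a, b in above:
            retained_ids[a.sample_id] = a
            retained_ids[b.sample_id] = b
        retained = list(retained_ids.values())
    return pd.concat([s.zscores for s in retained], axis=1).median(axis=1)


def expression_block(
    drug_vectors: pd.DataFrame, signature: GeneSignature
) -> FeatureMatrix:
    """One feature column per signature gene, tagged "expression"."""
    missing = [g for g in signature.genes if g not in drug_vectors.columns]
    if missing:
        raise KeyError(f"signature genes absent from gene universe: {missing}")
    sub = drug_vectors[list(signature.genes)]
    return FeatureMatrix(sub.copy(), {g: "expression" for g in signature.genes})
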