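#!/usr/bin/env python
"""Per-drug feature construction and class-level structure checks.

Reads the simulated inputs from 01, collapses the liver-condition samples
(PHH, 10 uM, >=24 h) to one z-score vector per drug, computes the Tanimoto
similarity matrix and the drug-target matrix, and reports the two
structural facts the downstream classifiers lean on: No-DILI drugs are
chemically more self-similar than Most-DILI drugs, and some targets are
hit mostly by DILI drugs.
"""

import itertools
import json
from pathlib import Path

import numpy as np

from dilipred import io as dio
from dilipred.chem import similarity_matrix
from dilipred.datatypes import DiliClass
from dilipred.expression import SampleFilter, collapse_to_drug, select_samples
from dilipred.targets import build_target_matrix, target_class_profile

BASE = Path(__file__).resolve().parents[1] / "results"
DATA, OUT = BASE / "data", BASE / "features"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    drugs = dio.read_gold_standard(DATA / "labels.tsv")
    samples = dio.read_expression_table(DATA / "expression.tsv")
    fps = dio.read_fingerprints(DATA / "fingerprints.tsv")
    targets = dio.read_targets(DATA / "targets.tsv")

    kept = select_samples(samples, SampleFilter())
    vec = collapse_to_drug(kept)
    vec.to_csv(OUT / "drug_expression.tsv", sep="\t", float_format="%.6g")
    print(f"{len(kept)}/{len(samples)} samples pass the PHH/10uM/>=24h filter; "
          f"{vec.shape[0]} drugs x {vec.shape[1]} genes")

    sim = similarity_matrix(fps)
    sim.to_csv(OUT / "tanimoto.tsv", sep="\t", float_format="%.4f")
    by_class = {d.drug_id: d.dili_class for d in drugs}
    for cls in (DiliClass.NO, DiliClass.MOST):
        ids = [d for d, c in by_class.items() if c is cls]
        mean = np.mean([sim.loc[a, b] for a, b in itertools.combinations(ids, 2)])
        print(f"mean within-class Tanimoto, {cls.value}: {mean:.3f}")

    mat, excluded = build_target_matrix(targets, [d.drug_id for d in drugs])
    prof = target_class_profile(mat, drugs)
    prof.to_csv(OUT / "target_profile.tsv", sep="\t", float_format="%.3f")
    truth = json.loads((DATA / "truth.json").read_text())
    enriched = [t for t in truth["enriched_targets"] if t in prof.index]
    background = [t for t in prof.index if t not in set(enriched)]
    print(f"{len(excluded)} drugs excluded for empty target sets: {excluded}")
    print("median DILI fraction, enriched targets:  "
          f"{prof.loc[enriched, 'dili_fraction'].median():.3f}")
    print("median DILI fraction, background targets: "
          f"{prof.loc[background, 'dili_fraction'].median():.3f}")


if __name__ == "__main__":
    main()
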