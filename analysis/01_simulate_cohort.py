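#!/usr/bin/env python
"""Generate the synthetic study cohort and write the five input files.

Emits a DILIrank-style label table (37 Most / 87 Less / 51 No / 55
Ambiguous), L1000-style expression signatures over the condition grid,
fingerprints, drug-target edges and phenotype gene sets, plus the ground
truth of the planted structure, under results/data/.
"""

import json
from dataclasses import asdict
from pathlib import Path

from dilipred import io as dio
from dilipred.datatypes import DiliClass
from dilipred.simulate import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    cohort = simulate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    dio.write_expression_table(cohort.samples, OUT / "expression.tsv")
    dio.write_gold_standard(cohort.drugs, OUT / "labels.tsv")
    dio.write_gene_sets(cohort.gene_sets, OUT / "gene_sets.gmt")
    dio.write_fingerprints(cohort.fingerprints, OUT / "fingerprints.tsv")
    dio.write_targets(cohort.targets, OUT / "targets.tsv")
    with open(OUT / "truth.json", "w") as fh:
        json.dump(asdict(cohort.truth), fh, indent=1, default=str)

    counts = {c.value: sum(d.dili_class is c for d in cohort.drugs) for c in DiliClass}
    print(f"cohort of {len(cohort.drugs)} drugs -> {OUT}")
    for name, n in counts.items():
        print(f"  {name:28s} {n}")
    print(f"  planted signal genes         {len(cohort.truth.signal_genes)}")
    print(f"  DILI-enriched targets        {len(cohort.truth.enriched_targets)}")
    print(f"  zero-target drugs            {cohort.truth.zero_target_drugs}")


if __name__ == "__main__":
    main()
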