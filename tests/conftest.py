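import numpy as np
import pandas as pd
import pytest

from dilipred.datatypes import ExpressionSample
from dilipred.simulate import SimulationConfig, simulate_cohort


def tiny_config(**overrides) -> SimulationConfig:
    """A small cohort that preserves the structure of the full design."""
    base = dict(
        n_most=6, n_less=10, n_no=8, n_ambiguous=5,
        n_genes=40, n_signal_genes=8,
        effect_size=2.0, perturb_fraction=0.5,
        n_replicates=2,
        fp_length=128, n_targets=30, n_enriched_targets=6,
        n_zero_target_labelled=1, n_zero_target_ambiguous=1,
        n_phenotypes=3, phenotype_size=12,
        seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(tiny_config())


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size study cohort (230 drugs, 978 genes)."""
    return simulate_cohort(SimulationConfig(seed=11))


def make_sample(sample_id, drug_id, cell_line, dose, time, values, genes=None):
    genes = genes or [f"G{i}" for i in range(len(values))]
    return ExpressionSample(
        sample_id, drug_id, cell_line, dose, time,
        pd.Series(np.asarray(values, dtype=float), index=genes),
    )
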