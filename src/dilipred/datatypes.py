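"""Domain types shared across the pipeline.

The cohort vocabulary follows DILIrank: every drug carries one of four
concern classes. For classification the four classes collapse to a binary
label — Most- and Less-DILI-Concern are the positive ("DILI") class,
No-DILI-Concern the negative — while Ambiguous-DILI-Concern drugs are never
used for training or testing and serve only as an independent hold-out set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to its expected layout."""


class DiliClass(enum.Enum):
    MOST = "Most-DILI-Concern"
    LESS = "Less-DILI-Concern"
    NO = "No-DILI-Concern"
    AMBIGUOUS = "Ambiguous-DILI-Concern"

    @classmethod
    def parse(cls, token: str) -> "DiliClass":
        """Case-insensitive parse; any unknown token is a hard error."""
        norm = token.strip().lower()
        for member in cls:
            if member.value.lower() == norm:
                return member
        raise FormatError(f"unknown DILI class token: {token!r}")

    @property
    def is_positive(self) -> bool:
        """Binary collapse: Most/Less -> DILI positive."""
        return self in (DiliClass.MOST, DiliClass.LESS)

    @property
    def is_labelled(self) -> bool:
        return self is not DiliClass.AMBIGUOUS


@dataclass
class DrugRecord:
    drug_id: str
    dili_class: DiliClass
    smiles: Optional[str] = None
    targets: Optional[frozenset[str]] = None

    @property
    def target_absent(self) -> bool:
        return self.targets is not None and len(self.targets) == 0


@dataclass(eq=False)  # identity equality: zscores Series defeats field-wise ==
class ExpressionSample:
    """One level-5 signature: moderated z-scores for one treatment condition."""

    sample_id: str
    drug_id: str
    cell_line: str
    dose: float  # µM
    time: float  # hours
    zscores: pd.Series  # index = gene ids

    @property
    def genes(self) -> pd.Index:
        return self.zscores.index


@dataclass
class GeneSet:
    phenotype_id: str
    phenotype_name: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSignature:
    """Ordered gene list with per-gene p-values and provenance.

    ``provenance`` is "wilcoxon" for signatures derived by the rank-sum
    differential test and "gene-set" for phenotype-derived ones (whose
    p-values are NaN).
    """

    genes: list[str]
    p_values: dict[str, float] = field(default_factory=dict)
    provenance: str = "wilcoxon"

    def __len__(self) -> int:
        return len(self.genes)


VALID_BLOCKS = ("expression", "chem", "target", "meta")


@dataclass
class FeatureMatrix:
    """Drugs × named feature columns with per-column block provenance."""

    values: pd.DataFrame  # index = drug ids
    blocks: dict[str, str]  # column name -> block tag

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.blocks)
        if missing:
            raise ValueError(f"columns without block tag: {sorted(missing)}")
        bad = set(self.blocks.values()) - set(VALID_BLOCKS)
        if bad:
            raise ValueError(f"unknown block tags: {sorted(bad)}")
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    def block(self, tag: str) -> pd.DataFrame:
        cols = [c for c in self.values.columns if self.blocks[c] == tag]
        return self.values[cols]

    def concat(self, other: "FeatureMatrix") -> "FeatureMatrix":
        """Column-concatenate two blocks over the same drugs (no rescaling)."""
        if list(self.values.index) != list(other.values.index):
            raise ValueError("feature blocks are not aligned on drug ids")
        overlap = set(self.values.columns) & set(other.values.columns)
        if overlap:
            raise ValueError(f"duplicate feature columns: {sorted(overlap)}")
        return FeatureMatrix(
            pd.concat([self.values, other.values], axis=1),
            {**self.blocks, **other.blocks},
        )

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)
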