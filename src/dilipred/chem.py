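"""Chemical-structure features: fingerprints and Tanimoto similarity.

Fingerprints are hashed path-based bit vectors (RDKit ``RDKFingerprint``),
deterministic for a given SMILES. The pipeline equally accepts precomputed
fingerprints, so chemistry parsing is optional. The feature encoding is a
drug's vector of Tanimoto similarities to the *training-pool* drugs only,
which keeps hold-out scoring free of test-information leakage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix

logger = logging.getLogger(__name__)


def fingerprint_from_smiles(smiles: str, fp_length: int = 1024) -> np.ndarray:
    """Hashed path-based binary fingerprint; raises ValueError on bad SMILES."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdmolops

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    bv = rdmolops.RDKFingerprint(mol, fpSize=fp_length)
    arr = np.zeros(fp_length, dtype=bool)
    arr[list(bv.GetOnBits())] = True
    return arr


def fingerprints_from_smiles(
    smiles_map: dict[str, str], fp_length: int = 1024
) -> dict[str, np.ndarray]:
    """Fingerprint every drug; unparsable SMILES drops the drug with a warning."""
    out = {}
    for drug_id, smi in smiles_map.items():
        try:
            out[drug_id] = fingerprint_from_smiles(smi, fp_length)
        except ValueError:
            logger.warning("drug %s excluded from chem block: unparsable SMILES", drug_id)
    return out


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b|; two empty fingerprints give 0 by convention."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        logger.warning("tanimoto of two empty fingerprints defined as 0")
        return 0.0
    return int(np.logical_and(a, b).sum()) / union


def similarity_matrix(fingerprints: dict[str, np.ndarray]) -> pd.DataFrame:
    """Symmetric pairwise Tanimoto matrix with unit diagonal."""
    if len(fingerprints) < 2:
        raise ValueError("need >=2 fingerprints")
    ids = list(fingerprints)
    mat = np.stack([np.asarray(fingerprints[i], dtype=bool) for i in ids])
    inter = (mat.astype(np.int32) @ mat.T.astype(np.int32)).astype(float)
    row_sums = mat.sum(axis=1)
    union = row_sums[:, None] + row_sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, [1.0 if s > 0 else 0.0 for s in row_sums])
    return pd.DataFrame(sim, index=ids, columns=ids)


def chem_block(sim: pd.DataFrame, reference_ids: list[str]) -> FeatureMatrix:
    """Each drug's features = its similarities to the reference (training) drugs."""
    missing = [r for r in reference_ids if r not in sim.columns]
    if missing:
        raise KeyError(f"reference drugs absent from similarity matrix: {missing}")
    cols = {f"sim_{r}": "chem" for r in reference_ids}
    block = sim[reference_ids].copy()
    block.columns = list(cols)
    return FeatureMatrix(block, cols)
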