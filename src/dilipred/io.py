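"""Readers and writers for the five external inputs.

All formats are UTF-8, tab-delimited text; lines starting with '#' are
ignored. Expression data is a flat TSV (one row per sample, one column per
gene) rather than any binary assay format, so cohorts remain plain text.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .datatypes import DiliClass, DrugRecord, ExpressionSample, FormatError, GeneSet

logger = logging.getLogger(__name__)

EXPRESSION_META_COLUMNS = ["sample_id", "drug_id", "cell_line", "dose_uM", "time_h"]


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


# ---------------------------------------------------------------------------
# Expression tables


def read_expression_table(path) -> list[ExpressionSample]:
    """Parse a sample × gene z-score table.

    Header: sample_id, drug_id, cell_line, dose_uM, time_h, then one column
    per gene. Returns one :class:`ExpressionSample` per row; the gene
    universe is the set of gene columns.
    """
    df = _read_tsv(path)
    for col in EXPRESSION_META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"expression table {path}: missing column {col!r}")
    gene_cols = [c for c in df.columns if c not in EXPRESSION_META_COLUMNS]
    if not gene_cols:
        raise FormatError(f"expression table {path}: no gene columns")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"duplicated sample_id: {dup.iloc[0]!r}")
    samples = []
    for _, row in df.iterrows():
        sid = row["sample_id"]
        try:
            z = pd.to_numeric(row[gene_cols]).astype(float)
            z.index = pd.Index(gene_cols)
            dose = float(row["dose_uM"])
            time = float(row["time_h"])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric value in sample {sid!r}: {exc}") from exc
        samples.append(
            ExpressionSample(sid, row["drug_id"], row["cell_line"], dose, time, z)
        )
    return samples


def write_expression_table(samples: list[ExpressionSample], path) -> None:
    if not samples:
        raise ValueError("no samples to write")
    genes = list(samples[0].genes)
    rows = []
    for s in samples:
        rec = {
            "sample_id": s.sample_id,
            "drug_id": s.drug_id,
            "cell_line": s.cell_line,
            "dose_uM": s.dose,
            "time_h": s.time,
        }
        rec.update(s.zscores.reindex(genes).to_dict())
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Gold-standard labels


def read_gold_standard(path) -> list[DrugRecord]:
    """Parse the drug_id → DILI-concern class table."""
    df = _read_tsv(path)
    for col in ("drug_id", "dili_class"):
        if col not in df.columns:
            raise FormatError(f"gold standard {path}: missing column {col!r}")
    if df.empty:
        logger.warning("gold standard %s is empty", path)
        return []
    dup = df["drug_id"][df["drug_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"duplicated drug_id: {dup.iloc[0]!r}")
    return [
        DrugRecord(row["drug_id"], DiliClass.parse(row["dili_class"]))
        for _, row in df.iterrows()
    ]


def write_gold_standard(drugs: list[DrugRecord], path) -> None:
    pd.DataFrame(
        {"drug_id": [d.drug_id for d in drugs],
         "dili_class": [d.dili_class.value for d in drugs]}
    ).to_csv(path, sep="\t", index=False)


def class_counts(drugs: list[DrugRecord]) -> dict[DiliClass, int]:
    counts = {c: 0 for c in DiliClass}
    for d in drugs:
        counts[d.dili_class] += 1
    return counts


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path, min_size: int = 10) -> list[GeneSet]:
    """Parse a GMT file; sets smaller than ``min_size`` are dropped."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            pid, name, *genes = fields
            genes = [g for g in genes if g]
            if len(genes) < min_size:
                logger.warning(
                    "gene set %s dropped: %d genes < min_size %d", pid, len(genes), min_size
                )
                continue
            sets.append(GeneSet(pid, name, frozenset(genes)))
    return sets


def write_gene_sets(sets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.phenotype_id, gs.phenotype_name, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# SMILES / fingerprints


def read_smiles(path) -> dict[str, str]:
    """Two-column TSV: drug_id, SMILES."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"SMILES file {path}: expected 2 columns")
    col_id, col_smi = df.columns[:2]
    return dict(zip(df[col_id], df[col_smi]))


def write_smiles(smiles: dict[str, str], path) -> None:
    pd.DataFrame({"drug_id": list(smiles), "smiles": list(smiles.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_fingerprints(path) -> dict[str, "pd.arrays.BooleanArray"]:
    """Two-column TSV: drug_id, bitstring of 0/1 characters."""
    import numpy as np

    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"fingerprint file {path}: expected 2 columns")
    out = {}
    lengths = set()
    for _, row in df.iterrows():
        bits = row.iloc[1]
        if set(bits) - {"0", "1"}:
            raise FormatError(f"fingerprint of {row.iloc[0]!r} is not a 0/1 string")
        vec = np.frombuffer(bits.encode(), dtype="u1") - ord("0")
        out[row.iloc[0]] = vec.astype(bool)
        lengths.add(len(vec))
    if len(lengths) > 1:
        raise FormatError(f"fingerprints of mixed lengths: {sorted(lengths)}")
    return out


def write_fingerprints(fps: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tbits\n")
        for did, bits in fps.items():
            fh.write(did + "\t" + "".join("1" if b else "0" for b in bits) + "\n")


# ---------------------------------------------------------------------------
# Drug-target edge lists


def read_targets(path) -> dict[str, frozenset[str]]:
    """Edge-list TSV (drug_id, protein_id[, source]); duplicates collapse."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"target file {path}: expected >=2 columns")
    col_d, col_t = df.columns[:2]
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row[col_d], set()).add(row[col_t])
    return {d: frozenset(t) for d, t in out.items()}


def write_targets(targets: dict[str, frozenset[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tprotein_id\n")
        for did in targets:
            for t in sorted(targets[did]):
                fh.write(f"{did}\t{t}\n")
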