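"""Reading and writing the quantification-table dialect, FASTA and reference lists.

The protein table dialect follows MaxQuant's ``proteinGroups.txt``: one row
per protein group, tab-separated, with ``LFQ intensity <sample>`` columns
(zero meaning not quantified), ``Reverse`` and ``Potential contaminant``
flag columns marked ``+``, and a ``Unique peptides`` count.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (
    FormatError,
    ExperimentDesign,
    IntensityMatrix,
    ProteinTable,
)
from .synthetic import AMINO_ACIDS

LFQ_PREFIX = "LFQ intensity "


def read_protein_groups(path) -> tuple[ProteinTable, IntensityMatrix]:
    """Parse a proteinGroups-dialect table.

    Returns the protein metadata and a raw-scale intensity matrix in which
    LFQ cells equal to zero are marked missing.  Semicolon-separated
    protein-group ids are collapsed to their leading (razor) id; the full
    group string is kept in the ``protein_group`` column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise FormatError(f"{path}: no '{LFQ_PREFIX}<sample>' columns found")
    for col in ("Protein IDs",):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    groups = df["Protein IDs"].astype(str)
    ids = groups.str.split(";").str[0]
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise FormatError(f"{path}: duplicated protein ids: {dups}")

    def _flag(col: str) -> pd.Series:
        if col not in df.columns:
            return pd.Series(False, index=df.index)
        return df[col].fillna("") == "+"

    n_unique = (
        pd.to_numeric(df["Unique peptides"], errors="coerce").fillna(0).astype(int)
        if "Unique peptides" in df.columns
        else pd.Series(0, index=df.index)
    )
    ptable = ProteinTable(
        pd.DataFrame(
            {
                "protein_id": ids.to_numpy(),
                "gene_name": df.get("Gene names", ids).fillna("").to_numpy(),
                "n_unique_peptides": n_unique.to_numpy(),
                "reverse": _flag("Reverse").to_numpy(),
                "contaminant": _flag("Potential contaminant").to_numpy(),
                "protein_group": groups.to_numpy(),
            }
        )
    )

    values = df[lfq_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    values[values == 0] = np.nan  # zero means not quantified
    sample_ids = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    matrix = IntensityMatrix(
        pd.DataFrame(values, index=ids.to_numpy(), columns=sample_ids), scale="raw"
    )
    return ptable, matrix


def write_protein_groups(path, ptable: ProteinTable, matrix: IntensityMatrix) -> None:
    """Write the proteinGroups dialect; missing cells become 0.

    A log2-scale matrix is exponentiated back to raw intensities so the
    file round-trips through :func:`read_protein_groups`.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if matrix.scale == "log2":
        vals = np.power(2.0, vals)
    out = pd.DataFrame(
        {
            "Protein IDs": ptable.table["protein_id"].to_numpy(),
            "Gene names": ptable.table["gene_name"].to_numpy(),
            "Unique peptides": ptable.table["n_unique_peptides"].to_numpy(),
            "Reverse": np.where(ptable.table["reverse"], "+", ""),
            "Potential contaminant": np.where(ptable.table["contaminant"], "+", ""),
        }
    )
    for j, sid in enumerate(matrix.sample_ids):
        col = vals[:, j].copy()
        col[np.isnan(col)] = 0.0
        out[LFQ_PREFIX + sid] = col
    out.to_csv(path, sep="\t", index=False)


def filter_proteins(
    ptable: ProteinTable,
    matrix: IntensityMatrix,
    design: ExperimentDesign,
    min_unique_peptides: int = 3,
    min_replicates: int = 2,
) -> tuple[ProteinTable, IntensityMatrix, dict[str, int]]:
    """Apply the screen's protein filters.

    Removes reverse hits and contaminants, proteins identified with fewer
    than ``min_unique_peptides`` unique peptides, and proteins not measured
    in at least ``min_replicates`` replicates of at least one
    (isoform, genotype) condition.  Rules are conjunctive, so application
    order does not affect the surviving set.  Returns the filtered table
    and matrix plus counts removed per rule (a row can count toward
    several rules).
    """
    tab = ptable.table.set_index("protein_id")
    ids = matrix.protein_ids
    tab = tab.loc[ids]

    decoy = (tab["reverse"] | tab["contaminant"]).to_numpy()
    few_peptides = (tab["n_unique_peptides"] < min_unique_peptides).to_numpy()

    observed = ~matrix.values.isna().to_numpy()
    labels = design.condition_labels.loc[matrix.sample_ids]
    enough = np.zeros(len(ids), dtype=bool)
    for cond in labels.unique():
        cols = np.flatnonzero((labels == cond).to_numpy())
        enough |= observed[:, cols].sum(axis=1) >= min_replicates

    keep = ~decoy & ~few_peptides & enough
    report = {
        "reverse_or_contaminant": int(decoy.sum()),
        "too_few_unique_peptides": int(few_peptides.sum()),
        "not_reproducibly_measured": int((~enough).sum()),
        "kept": int(keep.sum()),
        "removed": int((~keep).sum()),
    }
    kept_ids = [pid for pid, k in zip(ids, keep) if k]
    return ptable.subset(kept_ids), matrix.subset(kept_ids), report


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences; ids kept verbatim, residues uppercased."""
    with open(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or invalid FASTA")
    seqs: dict[str, str] = {}
    valid = set(AMINO_ACIDS)
    for rec in records:
        seq = str(rec.seq).upper()
        offenders = sorted({c for c in seq if c not in valid})
        if offenders:
            raise FormatError(
                f"{path}: record {rec.id} contains non-residue characters {offenders}"
            )
        seqs[rec.id] = seq
    return seqs


def write_fasta(path, seqs: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_list(path) -> set[str]:
    """One identifier per line (optional single header); duplicates dropped."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise FormatError(f"{path}: empty reference list")
    if lines[0].lower() in {"protein_id", "id", "uniprot", "accession"}:
        lines = lines[1:]
    return set(lines)


def write_reference_list(path, ids: Iterable[str]) -> None:
    Path(path).write_text("\n".join(sorted(set(ids))) + "\n")


def read_compartment_table(path) -> pd.DataFrame:
    """Compartment annotation TSV: protein id, compartment[, score].

    Multi-row annotations per protein are collapsed to the top-scoring
    call (ties: first listed), giving one neighborhood per protein.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise FormatError(f"{path}: expected at least two columns")
    df = df.rename(columns={cols[0]: "protein_id", cols[1]: "compartment"})
    if len(cols) >= 3:
        df = df.rename(columns={cols[2]: "score"})
        df = (
            df.sort_values("score", ascending=False, kind="stable")
            .drop_duplicates("protein_id")
            .reset_index(drop=True)
        )
    else:
        df = df.drop_duplicates("protein_id").reset_index(drop=True)
    return df[["protein_id", "compartment"]]
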