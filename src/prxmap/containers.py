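"""Shared data containers for the peroxiredoxin interactome pipeline.

The pipeline revolves around two objects: a protein-by-sample intensity
matrix with explicit missingness, and the experimental design mapping each
pull-down sample to its bait isoform, bait genotype and biological
replicate.  Missing label-free quantification (LFQ) values are represented
as ``NaN`` internally; the MaxQuant table dialect writes them as ``0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ISOFORMS = ("PRDX1", "PRDX2", "PRDX3", "PRDX4", "PRDX5")
#: Bait genotypes: wild type, resolving-cysteine mutant, catalytic-dead mutant.
GENOTYPES = ("WT", "CRS", "CPRS")

RAW = "raw"
LOG2 = "log2"


class FormatError(ValueError):
    """Raised when an input table violates the expected dialect."""


@dataclass
class IntensityMatrix:
    """Proteins x samples LFQ intensities with explicit missing values.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample.
        ``NaN`` marks a missing (not-quantified) cell.
    scale
        ``"raw"`` for intensities as exported by the quantification
        software, ``"log2"`` after log transformation.
    """

    values: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        self.values = self.values.astype(float)
        if self.scale == RAW:
            observed = self.values.to_numpy()
            if np.nanmin(observed, initial=np.inf) < 0:
                raise ValueError("raw intensities must be non-negative")

    @property
    def missing(self) -> pd.DataFrame:
        """Boolean mask, True where the value is missing."""
        return self.values.isna()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self, per_sample: bool = False):
        mask = self.missing
        return mask.mean(axis=0) if per_sample else float(mask.to_numpy().mean())

    def subset(self, protein_ids: Iterable[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.values.loc[list(protein_ids)], scale=self.scale)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), scale=self.scale)


@dataclass
class ExperimentDesign:
    """Sample -> (isoform, genotype, replicate) assignment.

    The design is stored as a DataFrame indexed by sample id with columns
    ``isoform``, ``genotype`` and ``replicate``.  A *condition* is an
    (isoform, genotype) pair, written ``"PRDX1:WT"``; it is the unit the
    dropout model estimates a mean for.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"isoform", "genotype", "replicate"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        trip = self.table[["isoform", "genotype", "replicate"]]
        if trip.duplicated().any():
            dup = trip[trip.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate (isoform, genotype, replicate) triple: {tuple(dup)}"
            )
        bad = set(self.table["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes: {sorted(bad)}")

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, tuple[str, str, int]]
    ) -> "ExperimentDesign":
        rows = {
            sid: {"isoform": iso, "genotype": gt, "replicate": rep}
            for sid, (iso, gt, rep) in mapping.items()
        }
        return cls(pd.DataFrame.from_dict(rows, orient="index"))

    @classmethod
    def full_design(
        cls,
        isoforms: Sequence[str] = ISOFORMS,
        genotypes: Sequence[str] = GENOTYPES,
        n_replicates: int = 3,
    ) -> "ExperimentDesign":
        """The study layout: every isoform x genotype with ``n_replicates``."""
        mapping = {
            f"{iso}_{gt}_{rep}": (iso, gt, rep)
            for iso in isoforms
            for gt in genotypes
            for rep in range(1, n_replicates + 1)
        }
        return cls.from_mapping(mapping)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def isoforms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iso in self.table["isoform"]:
            seen.setdefault(iso, None)
        return list(seen)

    def condition_of(self, sample_id: str) -> str:
        row = self.table.loc[sample_id]
        return f"{row['isoform']}:{row['genotype']}"

    @property
    def condition_labels(self) -> pd.Series:
        return self.table["isoform"].str.cat(self.table["genotype"], sep=":")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.condition_labels:
            seen.setdefault(lab, None)
        return list(seen)

    def samples_in(self, condition: str) -> list[str]:
        labels = self.condition_labels
        return list(labels.index[labels == condition])

    def subset(self, sample_ids: Iterable[str]) -> "ExperimentDesign":
        return ExperimentDesign(self.table.loc[list(sample_ids)])

    def relabel(self, genotype_map: Mapping[str, str]) -> "ExperimentDesign":
        """Return a design with per-sample genotype labels replaced.

        Used by permutation calibration to shuffle WT/mutant labels while
        keeping the isoform structure intact.  Replicate indices are
        renumbered within each (isoform, genotype) so the relabeled design
        still satisfies the uniqueness invariant.
        """
        new = self.table.copy()
        for sid, gt in genotype_map.items():
            new.loc[sid, "genotype"] = gt
        counters: dict[tuple[str, str], int] = {}
        for sid in new.index:
            key = (new.loc[sid, "isoform"], new.loc[sid, "genotype"])
            counters[key] = counters.get(key, 0) + 1
            new.loc[sid, "replicate"] = counters[key]
        return ExperimentDesign(new)


@dataclass
class ProteinTable:
    """Per-protein metadata in the quantification-software dialect."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("protein_id", "gene_name", "n_unique_peptides", "reverse", "contaminant")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"protein table missing columns {sorted(missing)}")
        ids = self.table["protein_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise FormatError(f"duplicated protein ids: {dups}")
        if (self.table["n_unique_peptides"] < 0).any():
            raise ValueError("negative unique-peptide count")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.table["protein_id"])

    def subset(self, protein_ids: Iterable[str]) -> "ProteinTable":
        keep = self.table.set_index("protein_id").loc[list(protein_ids)].reset_index()
        return ProteinTable(keep)
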