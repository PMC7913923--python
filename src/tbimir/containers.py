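"""Shared in-memory containers for the plasma-miRNA pipeline.

The pipeline starts from a miRNA read-count matrix (miRNAs x samples) with
per-sample totals of miRNA-mapped reads, sample metadata (group labels,
hemolysis coefficients, covariates), and RT-qPCR Cq tables. These thin
wrappers around pandas objects enforce the invariants every downstream
stage relies on (non-negative integer counts, positive totals, aligned
sample ids) and centralise TSV/CSV round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "SampleMeta", "CqTable", "AssayRole"]


class AssayRole:
    """Roles an RT-qPCR assay can play in the analysis."""

    TARGET = "target"
    REFERENCE = "reference"
    HEMOLYSIS_23A = "hemolysis_23a"
    HEMOLYSIS_451 = "hemolysis_451"
    SPIKE_IN = "spike_in"


@dataclass
class SampleMeta:
    """Per-sample metadata table.

    ``table`` is indexed by sample id and carries at least a ``group``
    column; optional columns used by QC and the clinical analyses are
    ``a414`` (hemolysis absorbance coefficient at 414 nm), ``hemolyzed``
    (planted ground-truth flag from the simulator), ``s100b`` (ug/L),
    ``hours_to_sampling``, ``sex`` and ``age``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise ValueError("sample metadata must have a 'group' column")
        if not self.table.index.is_unique:
            raise ValueError("sample ids must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def group_sizes(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMeta":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))


@dataclass
class CountMatrix:
    """Raw miRNA read counts (miRNAs in rows, samples in columns).

    ``mirna_mapped_total`` holds, per sample, the total number of reads
    mapped to miRNAs — the denominator of the counts-per-million formula.
    Totals may exceed the in-matrix column sums (the matrix may have been
    filtered) but must be strictly positive.
    """

    counts: pd.DataFrame
    mirna_mapped_total: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.empty:
            raise ValueError("count matrix is empty")
        if not counts.index.is_unique or not counts.columns.is_unique:
            raise ValueError("miRNA ids and sample ids must be unique")
        values = counts.to_numpy()
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        totals = self.mirna_mapped_total.reindex(counts.columns)
        if totals.isna().any():
            missing = list(totals.index[totals.isna()])
            raise ValueError(f"missing miRNA-mapped totals for samples: {missing}")
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise ValueError(f"non-positive miRNA-mapped totals for samples: {bad}")
        self.mirna_mapped_total = totals.astype(float)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_mirnas(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.counts[ids].copy(), self.mirna_mapped_total[ids].copy())

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.loc["__mirna_mapped_total__"] = self.mirna_mapped_total
        out.to_csv(path, sep="\t", index_label="mirna_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        table = pd.read_csv(path, sep="\t", index_col="mirna_id")
        if "__mirna_mapped_total__" in table.index:
            totals = table.loc["__mirna_mapped_total__"]
            counts = table.drop(index="__mirna_mapped_total__")
        else:
            counts = table
            totals = table.sum(axis=0)
        return cls(counts.astype(int), totals.astype(float))

    @classmethod
    def from_counts(cls, counts: pd.DataFrame,
                    totals: Mapping[str, float] | pd.Series | None = None) -> "CountMatrix":
        """Build a matrix; totals default to the in-matrix column sums."""
        if totals is None:
            totals = counts.sum(axis=0)
        return cls(counts, pd.Series(totals))


@dataclass
class CqTable:
    """RT-qPCR quantification cycles, samples in rows, assays in columns.

    ``roles`` maps each assay to its role (target, reference, hemolysis
    pair member, spike-in). NaN marks a failed/missing reaction.
    """

    cq: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cq.index.is_unique or not self.cq.columns.is_unique:
            raise ValueError("sample ids and assay names must be unique")
        unknown = set(self.roles) - set(self.cq.columns)
        if unknown:
            raise ValueError(f"roles refer to assays not in the table: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cq.index)

    @property
    def assays(self) -> list[str]:
        return list(self.cq.columns)

    def assays_with_role(self, role: str) -> list[str]:
        return [a for a, r in self.roles.items() if r == role]

    def reference_assay(self) -> str:
        refs = self.assays_with_role(AssayRole.REFERENCE)
        if not refs:
            raise ValueError("no assay with the reference role")
        return refs[0]

    def to_csv(self, path: str | Path) -> None:
        out = self.cq.copy()
        out.columns = [
            f"{a}|{self.roles.get(a, AssayRole.TARGET)}" for a in out.columns
        ]
        out.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CqTable":
        table = pd.read_csv(path, index_col="sample_id")
        roles: dict[str, str] = {}
        names = []
        for col in table.columns:
            name, _, role = col.partition("|")
            names.append(name)
            roles[name] = role or AssayRole.TARGET
        table.columns = names
        return cls(table, roles)
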