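"""Readers and writers for the tabular and sequence formats the pipeline touches.

Count tables are TSV with one header row and one id column, stored with OTUs
as rows and samples as columns (the amplicon convention); an orientation flag
handles tables supplied the other way around.  Sample metadata is CSV with a
fixed header.  All round trips are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "CountTable",
    "METADATA_COLUMNS",
    "read_count_table",
    "write_count_table",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "read_life_history",
    "write_life_history",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


METADATA_COLUMNS = [
    "sample_id",
    "family_id",
    "dam_id",
    "sire_id",
    "dam_population",
    "sire_population",
    "mortality_class",
]

LIFE_HISTORY_COLUMNS = [
    "family_id",
    "replicate",
    "dam_id",
    "sire_id",
    "culture_alive",
    "larval_weight_ug",
    "settled",
    "survived",
]

_POPULATIONS = {"O", "W"}
_MORTALITY_CLASSES = {"high", "low", "unassigned"}


@dataclass
class CountTable:
    """Integer OTU x sample abundance matrix.

    ``counts`` has OTUs as rows and samples as columns.  ``otu_annotation``
    optionally maps OTU ids to a clade/type label (e.g. ``"C1"``).
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    otu_annotation: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        n_otu, n_samp = self.counts.shape
        if n_otu != len(self.otu_ids) or n_samp != len(self.sample_ids):
            raise FormatError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.otu_ids)} OTU ids and {len(self.sample_ids)} sample ids"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: list[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(
            otu_ids=list(self.otu_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx].copy(),
            otu_annotation=self.otu_annotation,
        )


def read_count_table(path: str | Path, orientation: str = "otus_by_samples") -> CountTable:
    """Read a TSV count table and return it in OTUs-by-samples orientation.

    Parameters
    ----------
    path
        Tab-separated file with one header row and the id column first.
    orientation
        ``"otus_by_samples"`` if rows are OTUs (default), ``"samples_by_otus"``
        if rows are samples; the latter is transposed on intake.
    """
    if orientation not in ("otus_by_samples", "samples_by_otus"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate row or column ids")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell: {exc}") from None
    if np.any(np.isnan(values)):
        raise FormatError(f"{path}: missing cell")
    if not np.all(np.equal(np.mod(values, 1), 0)):
        raise FormatError(f"{path}: non-integer count")
    if np.any(values < 0):
        raise FormatError(f"{path}: negative count")
    counts = values.astype(np.int64)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if orientation == "samples_by_otus":
        counts = counts.T
        row_ids, col_ids = col_ids, row_ids
    return CountTable(otu_ids=row_ids, sample_ids=col_ids, counts=counts)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="otu_id")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ``{otu_id: sequence}`` map.

    Ids are the header up to the first whitespace; sequences are upper-cased.
    Duplicate ids and empty records are format errors.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA header {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {record.id!r}")
        seqs[record.id] = seq
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table (see ``METADATA_COLUMNS``).

    Enforces unique sample ids, one (dam, sire) pair per family, valid
    population codes and mortality classes, and no missing parental fields.
    """
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    df = df[METADATA_COLUMNS].astype(str)
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in metadata")
    for col in ("family_id", "dam_id", "sire_id"):
        if (df[col].isin(["nan", ""])).any():
            raise FormatError(f"missing values in metadata column {col}")
    bad_pop = set(df["dam_population"]) | set(df["sire_population"])
    if not bad_pop <= _POPULATIONS:
        raise FormatError(f"invalid population codes: {sorted(bad_pop - _POPULATIONS)}")
    bad_cls = set(df["mortality_class"]) - _MORTALITY_CLASSES
    if bad_cls:
        raise FormatError(f"invalid mortality classes: {sorted(bad_cls)}")
    pairs = df.groupby("family_id")[["dam_id", "sire_id"]].nunique()
    if (pairs > 1).any().any():
        raise FormatError("a family maps to more than one (dam, sire) pair")
    return df.reset_index(drop=True)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, dtype=str))


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(df).to_csv(path, index=False)


def read_life_history(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LIFE_HISTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"life-history table missing columns: {missing}")
    for col in ("settled", "survived"):
        if (df[col] < 0).any():
            raise FormatError(f"negative values in {col}")
    if (df["survived"] > df["settled"]).any():
        warnings.warn("life history has survivors exceeding settlers", stacklevel=2)
    return df


def write_life_history(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
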