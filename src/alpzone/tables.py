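"""Core data containers and text I/O for the metabarcoding pipeline.

The central object is the :class:`MOTUTable`: a MOTU x PCR read-count matrix
with per-MOTU annotations (sequence, amplicon length, taxonomy).  PCR metadata
and per-sample environmental variables travel as plain :class:`pandas.DataFrame`
objects with fixed column conventions, mirroring OBITools-style tab-separated
exports so that real tables and synthetic tables share one schema.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Annotation columns recognised in a MOTU table, in canonical order.
ANNOTATION_COLUMNS = (
    "sequence",
    "length",
    "class",
    "genus",
    "species",
    "clade_path",
    "is_contaminant",
    "is_mock",
)

#: PCR metadata columns.
PCR_COLUMNS = ("pcr_id", "sample_id", "marker", "replicate", "control_type")

#: Valid control types for a PCR.
CONTROL_TYPES = ("sample", "extraction_blank", "pcr_blank", "positive")


@dataclass
class MOTUTable:
    """MOTU x PCR read counts plus per-MOTU annotations.

    Parameters
    ----------
    annotations:
        One row per MOTU (index = MOTU id).  Any subset of
        :data:`ANNOTATION_COLUMNS` may be present; extra columns are carried
        through untouched.
    counts:
        Integer read counts, one row per MOTU (same index as ``annotations``),
        one column per PCR id.
    """

    annotations: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.annotations.index.equals(self.counts.index):
            raise ValueError("annotations and counts must share the same MOTU index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        if "sequence" in self.annotations and "length" in self.annotations:
            seq = self.annotations["sequence"]
            has_seq = seq.notna()
            mism = self.annotations.loc[has_seq, "length"] != seq[has_seq].str.len()
            if mism.any():
                bad = list(self.annotations.index[has_seq][mism][:3])
                raise ValueError(f"length does not match sequence length for {bad}")

    @property
    def motu_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def pcr_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_motus(self) -> int:
        return len(self.counts.index)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def subset_motus(self, keep: Iterable) -> "MOTUTable":
        keep = pd.Index(keep)
        return MOTUTable(self.annotations.loc[keep].copy(), self.counts.loc[keep].copy())

    def subset_pcrs(self, keep: Iterable) -> "MOTUTable":
        keep = [c for c in self.counts.columns if c in set(keep)]
        return MOTUTable(self.annotations.copy(), self.counts[keep].copy())

    def relative_frequencies(self) -> pd.DataFrame:
        """Per-PCR relative read frequencies (columns sum to 1; empty PCRs stay 0)."""
        totals = self.counts.sum(axis=0)
        freq = self.counts.div(totals.where(totals > 0, 1.0), axis=1)
        return freq.astype(float)


@dataclass
class QCReport:
    """Bookkeeping for one filtering stage."""

    stage: str
    motus_removed: int = 0
    pcrs_removed: int = 0
    reads_removed: int = 0
    details: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "stage": self.stage,
            "motus_removed": self.motus_removed,
            "pcrs_removed": self.pcrs_removed,
            "reads_removed": self.reads_removed,
        }


def validate_pcrs(pcrs: pd.DataFrame) -> pd.DataFrame:
    """Check a PCR metadata table and return it with canonical dtypes."""
    missing = [c for c in PCR_COLUMNS if c not in pcrs.columns]
    if missing:
        raise ValueError(f"PCR metadata is missing columns {missing}")
    bad = set(pcrs["control_type"]) - set(CONTROL_TYPES)
    if bad:
        raise ValueError(f"unknown control types {sorted(bad)}")
    samples = pcrs[pcrs["control_type"] == "sample"]
    dup = samples.duplicated(subset=["sample_id", "marker", "replicate"])
    if dup.any():
        raise ValueError("replicate indices must be unique within a sample and marker")
    return pcrs.reset_index(drop=True)


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

def write_motu_table(table: MOTUTable, path: str | Path) -> None:
    """Write a MOTU table as tab-separated text (annotations first, counts last)."""
    ann = table.annotations.copy()
    ordered = [c for c in ANNOTATION_COLUMNS if c in ann.columns]
    ordered += [c for c in ann.columns if c not in ordered]
    out = pd.concat([ann[ordered], table.counts], axis=1)
    out.index.name = "motu_id"
    out.to_csv(path, sep="\t")


def read_motu_table(path: str | Path, pcr_ids: Iterable | None = None) -> MOTUTable:
    """Read a tab-separated MOTU table.

    ``pcr_ids`` distinguishes count columns from annotation columns; when
    omitted, every column not in :data:`ANNOTATION_COLUMNS` is taken as counts.
    """
    df = pd.read_csv(path, sep="\t", index_col="motu_id")
    if pcr_ids is not None:
        count_cols = [c for c in df.columns if c in set(pcr_ids)]
    else:
        count_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    ann_cols = [c for c in df.columns if c not in count_cols]
    counts = df[count_cols].astype(np.int64)
    return MOTUTable(df[ann_cols], counts)


def read_pcr_table(path: str | Path) -> pd.DataFrame:
    return validate_pcrs(pd.read_csv(path))


def write_pcr_table(pcrs: pd.DataFrame, path: str | Path) -> None:
    validate_pcrs(pcrs).to_csv(path, index=False)


def read_env_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_env_table(env: pd.DataFrame, path: str | Path) -> None:
    out = env.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# annotated FASTA (`key=value; ` attribute dialect used by OBITools exports)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r"(\w+)=([^;]*);")


def write_annotated_fasta(table: MOTUTable, path: str | Path) -> None:
    """Write MOTUs with sequences as FASTA, annotations as `key=value; ` headers."""
    with open(path, "w") as fh:
        for motu_id, row in table.annotations.iterrows():
            seq = row.get("sequence")
            if not isinstance(seq, str):
                continue
            attrs = []
            for key in ("length", "class", "genus", "species", "clade_path"):
                val = row.get(key)
                if pd.notna(val):
                    attrs.append(f"{key}={val};")
            count = int(table.counts.loc[motu_id].sum())
            attrs.append(f"count={count};")
            fh.write(f">{motu_id} {' '.join(attrs)}\n{seq}\n")


def parse_fasta_annotations(path: str | Path) -> pd.DataFrame:
    """Parse `key=value; ` FASTA headers into an annotation frame (index = id)."""
    from Bio import SeqIO  # local import: only needed for FASTA input

    rows: dict[str, dict] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        attrs: Mapping[str, str] = dict(_ATTR_RE.findall(record.description))
        row: dict = {"sequence": str(record.seq)}
        for key, val in attrs.items():
            row[key] = val
        if "length" in row:
            row["length"] = int(row["length"])
        rows[record.id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "motu_id"
    return df
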