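"""Readers and writers for the tabular and FASTA formats the pipeline touches.

All tables are tab-separated with a mandatory header row, "." as the decimal
point and no thousands separators. FASTA follows the miRBase mature-sequence
dialect: the id is the header token before the first whitespace, the rest of
the header is a free-text description that is retained but unused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"

#: IUPAC degenerate RNA codes (U in place of T).
IUPAC_RNA = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU",
    "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
    "N": "ACGU",
}

COMPARTMENTS = ("cell", "EV")
CONDITIONS = ("CONT", "CAVIN1")


class FormatError(ValueError):
    """A file violated the expected on-disk contract."""


def normalize_rna(seq: str, *, context: str = "") -> str:
    """Uppercase, map T->U and check the strict {A,C,G,U} alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(RNA_ALPHABET)
    if bad:
        raise FormatError(
            f"non-IUPAC RNA character(s) {sorted(bad)}"
            + (f" in record {context!r}" if context else "")
        )
    return s


@dataclass
class SequenceSet:
    """Ordered id -> RNA sequence map over the strict {A,C,G,U} alphabet."""

    sequences: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for sid, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for id {sid!r}")
            clean[sid] = normalize_rna(seq, context=sid)
        self.sequences = clean

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __getitem__(self, sid: str) -> str:
        return self.sequences[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self.sequences

    def items(self):
        return self.sequences.items()

    def ids(self) -> list[str]:
        return list(self.sequences)

    def subset(self, ids) -> "SequenceSet":
        missing = [i for i in ids if i not in self.sequences]
        if missing:
            raise KeyError(f"ids absent from SequenceSet: {missing[:5]}")
        return SequenceSet(
            {i: self.sequences[i] for i in ids},
            {i: self.descriptions.get(i, "") for i in ids},
        )


@dataclass
class CountMatrix:
    """Integer miRNA x sample counts plus per-sample design metadata.

    ``counts`` is indexed by miRNA id with one column per sample;
    ``sample_meta`` is indexed by sample id with columns
    ``compartment`` ({cell, EV}), ``condition`` ({CONT, CAVIN1}) and
    ``replicate``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][:5].tolist()
            raise FormatError(f"duplicate miRNA ids: {dup}")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise FormatError(f"samples missing metadata: {missing}")
        self.sample_meta = self.sample_meta.loc[self.counts.columns]
        for col, allowed in (("compartment", COMPARTMENTS), ("condition", CONDITIONS)):
            if col not in self.sample_meta.columns:
                raise FormatError(f"sample metadata lacks column {col!r}")
            bad = set(self.sample_meta[col]) - set(allowed)
            if bad:
                raise FormatError(f"invalid {col} value(s): {sorted(bad)}")

    @property
    def mirna_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    def subset_samples(self, mask: pd.Series) -> "CountMatrix":
        keep = self.sample_meta.index[mask]
        return CountMatrix(self.counts[keep].copy(), self.sample_meta.loc[keep].copy())

    def compartment(self, which: str) -> "CountMatrix":
        if which not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {which!r}")
        return self.subset_samples(self.sample_meta["compartment"] == which)


@dataclass
class IntensityTable:
    """Positive protein x sample intensities with an early/metastatic grouping."""

    intensities: pd.DataFrame
    groups: pd.Series  # sample id -> {early, metastatic}

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() <= 0).any():
            raise FormatError("intensities must be strictly positive")
        missing = [s for s in self.intensities.columns if s not in self.groups.index]
        if missing:
            raise FormatError(f"samples missing group labels: {missing}")
        extra = [s for s in self.groups.index if s not in self.intensities.columns]
        if extra:
            raise FormatError(f"group file names unknown sample(s): {extra}")
        self.groups = self.groups.loc[self.intensities.columns]
        labels = set(self.groups)
        if len(labels) < 2:
            raise FormatError("both groups must be non-empty")

    @property
    def protein_ids(self) -> list[str]:
        return self.intensities.index.tolist()

    def group_columns(self, label: str) -> list[str]:
        return self.groups.index[self.groups == label].tolist()


# ---------------------------------------------------------------------------
# FASTA


def read_mature_fasta(path) -> SequenceSet:
    """Read a miRBase-style mature FASTA into a :class:`SequenceSet`.

    T/t is normalized to U and lowercase is uppercased; duplicate ids and
    characters outside {A,C,G,U} (after normalization) raise
    :class:`FormatError`.
    """
    seqs: dict[str, str] = {}
    descs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = normalize_rna(str(rec.seq), context=rec.id)
        desc = rec.description
        descs[rec.id] = desc[len(rec.id):].strip() if desc.startswith(rec.id) else desc
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return SequenceSet(seqs, descs)


def write_fasta(seqs: SequenceSet, path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description=seqs.descriptions.get(sid, ""))
        for sid, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# count tables


def read_count_table(path, meta_path) -> CountMatrix:
    """Read a tab-separated count table and its sample-metadata table."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    vals = raw.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        frac = vals != np.floor(vals)
        if frac.any():
            i, j = np.argwhere(frac)[0]
            raise FormatError(
                f"non-integer count {vals[i, j]!r} at miRNA {raw.index[i]!r}, "
                f"sample {raw.columns[j]!r}"
            )
        raw = raw.astype(np.int64)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(raw, meta)


def write_count_table(cm: CountMatrix, path, meta_path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="mirna_id")
    cm.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# intensity tables


def read_intensity_table(path, groups_path) -> IntensityTable:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    if (tab.to_numpy() <= 0).any():
        bad = tab.index[(tab <= 0).any(axis=1)][:5].tolist()
        raise FormatError(f"non-positive intensity for protein(s) {bad}")
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    return IntensityTable(tab, groups)


def write_intensity_table(table: IntensityTable, path, groups_path) -> None:
    table.intensities.to_csv(path, sep="\t", index_label="protein_id")
    table.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample_id")


def write_results(frame: pd.DataFrame, path, *, index_label: str | None = None) -> None:
    """Write a result table: header always present, deterministic column order,
    full-precision reals (pandas repr round-trips float64)."""
    frame.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def read_log2fc_table(path, *, id_col: str = "id", fc_col: str = "log2fc") -> pd.Series:
    """Read an externally supplied per-miRNA log2 fold-change table."""
    tab = pd.read_csv(path, sep="\t")
    for col in (id_col, fc_col):
        if col not in tab.columns:
            raise FormatError(f"log2fc table lacks column {col!r}")
    if tab[id_col].duplicated().any():
        raise FormatError("duplicate ids in log2fc table")
    return pd.Series(tab[fc_col].to_numpy(float), index=tab[id_col], name=fc_col)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
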