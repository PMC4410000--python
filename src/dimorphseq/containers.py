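"""Core in-memory containers: gene annotation, count matrices, TSS window signal.

Coordinates are 0-based half-open throughout (BED convention); GTF input is
converted on read. Chromosome class (X / Y / autosome) is always derived from
the chromosome name, never stored independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DimorphSeqError, FormatError

VALID_SEXES = ("male", "female", "unknown")


def chromosome_class(chrom: str) -> str:
    """Classify a chromosome name as ``"X"``, ``"Y"`` or ``"autosome"``.

    Recognises UCSC-style names (``chrX``) and bare names (``X``),
    case-insensitively.
    """
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.upper() == "X":
        return "X"
    if name.upper() == "Y":
        return "Y"
    return "autosome"


@dataclass
class GeneAnnotation:
    """Gene coordinates with derived chromosome class.

    Parameters
    ----------
    table : pandas.DataFrame
        Indexed by gene id with columns ``chrom`` (str), ``start`` (int),
        ``end`` (int), ``strand`` ("+" or "-"). A ``cls`` column
        (X / Y / autosome) is derived on construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "start", "end", "strand"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if (t["start"] >= t["end"]).any():
            bad = t.index[t["start"] >= t["end"]][0]
            raise FormatError(f"gene {bad!r} has start >= end")
        if (~t["strand"].isin(["+", "-"])).any():
            bad = t.index[~t["strand"].isin(["+", "-"])][0]
            raise FormatError(f"gene {bad!r} has invalid strand {t.loc[bad, 'strand']!r}")
        t = t.copy()
        t["cls"] = t["chrom"].map(chromosome_class)
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def tss(self) -> pd.Series:
        """Transcription start site: ``start`` on the + strand, ``end`` on −."""
        plus = self.table["strand"] == "+"
        return self.table["start"].where(plus, self.table["end"]).rename("tss")

    def genes_of_class(self, cls: str) -> list[str]:
        return list(self.table.index[self.table["cls"] == cls])

    @property
    def x_genes(self) -> list[str]:
        return self.genes_of_class("X")

    @property
    def y_genes(self) -> list[str]:
        return self.genes_of_class("Y")

    @property
    def autosomal_genes(self) -> list[str]:
        return self.genes_of_class("autosome")


@dataclass
class CountMatrix:
    """Integer gene × sample read counts plus per-sample metadata.

    ``counts`` is genes (rows) × samples (columns); ``metadata`` is indexed by
    sample id with columns ``sex`` (male / female / unknown) and ``stage``.
    Columns are reordered to follow the metadata.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        counts, meta = self.counts, self.metadata
        if "sex" not in meta.columns:
            raise FormatError("metadata must have a 'sex' column")
        if "stage" not in meta.columns:
            meta = meta.copy()
            meta["stage"] = "unspecified"
        bad_sex = set(meta["sex"]) - set(VALID_SEXES)
        if bad_sex:
            raise FormatError(f"invalid sex labels: {sorted(bad_sex)}")
        extra = [s for s in counts.columns if s not in meta.index]
        absent = [s for s in meta.index if s not in counts.columns]
        if extra or absent:
            raise FormatError(
                "metadata/count column mismatch: "
                f"samples only in counts {extra}, only in metadata {absent}"
            )
        if not np.issubdtype(counts.to_numpy().dtype, np.integer):
            arr = counts.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                r, c = np.argwhere(arr != np.round(arr))[0]
                raise FormatError(
                    f"non-integer count at gene {counts.index[r]!r}, "
                    f"sample {counts.columns[c]!r}: {arr[r, c]!r}"
                )
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise FormatError("negative counts are not allowed")
        self.counts = counts.loc[:, meta.index]
        self.metadata = meta

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.metadata.index

    @property
    def sex(self) -> pd.Series:
        return self.metadata["sex"]

    def samples_of_sex(self, sex: str) -> list[str]:
        if sex not in VALID_SEXES:
            raise DimorphSeqError(f"unknown sex label {sex!r}")
        return list(self.metadata.index[self.metadata["sex"] == sex])

    def with_sex(self, calls: pd.Series) -> "CountMatrix":
        """Return a copy whose metadata sexes are replaced by ``calls``."""
        meta = self.metadata.copy()
        meta.loc[calls.index, "sex"] = calls
        return CountMatrix(self.counts.copy(), meta)


@dataclass
class TSSWindowCounts:
    """Per-gene ChIP-seq signal in a symmetric window around each TSS.

    ``values`` holds the mean (``kind="average"``) or summed
    (``kind="total"``) coverage over TSS ± ``halfwidth`` for every annotated
    gene; ``total_excl_y`` is the genome-wide sum of ``values`` over all
    non-chrY genes, the library total used by the dosage model.
    """

    values: pd.Series
    sex: str
    halfwidth: int = 1500
    kind: str = "average"
    total_excl_y: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise DimorphSeqError(f"unknown sex label {self.sex!r}")
        if self.kind not in ("average", "total"):
            raise DimorphSeqError(f"kind must be 'average' or 'total', got {self.kind!r}")
        if (self.values < 0).any():
            raise DimorphSeqError("TSS window values must be non-negative")
        self.values = self.values.astype(float)
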