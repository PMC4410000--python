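"""Readers and writers for the plain-text formats the pipeline touches.

Formats: BED6 and GTF-subset gene annotation, TSV count matrices with a
sample-metadata sheet, 4-column bedGraph coverage, newline-delimited gene
lists and GMT pathway collections. Internal coordinates are 0-based
half-open; GTF (1-based inclusive) is converted on read.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneAnnotation, TSSWindowCounts
from .exceptions import DegenerateInputError, FormatError

logger = logging.getLogger(__name__)

_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_annotation(path: str | Path, format: str = "bed") -> GeneAnnotation:
    """Read gene annotation from a BED6 or GTF-subset file.

    BED is taken as-is (0-based half-open); GTF coordinates (1-based,
    end-inclusive) are converted. For GTF every line is treated as one gene
    record and the ``gene_id`` attribute supplies the id.
    """
    fmt = format.lower()
    if fmt == "bed":
        return _read_bed(path)
    if fmt == "gtf":
        return _read_gtf(path)
    raise FormatError(f"unknown annotation format {format!r} (expected 'bed' or 'gtf')")


def _read_bed(path: str | Path) -> GeneAnnotation:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 BED columns, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            records.append((name, chrom, start_i, end_i, strand))
    return _to_annotation(records, path)


def _read_gtf(path: str | Path) -> GeneAnnotation:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns, got {len(parts)}")
            chrom, _src, _feat, start, end, _score, strand, _frame, attrs = parts[:9]
            m = _GTF_GENE_ID.search(attrs)
            if m is None:
                raise FormatError(f"{path}:{lineno}: no gene_id attribute")
            try:
                # GTF is 1-based inclusive -> 0-based half-open
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            records.append((m.group(1), chrom, start_i, end_i, strand))
    return _to_annotation(records, path)


def _to_annotation(records: list[tuple], path) -> GeneAnnotation:
    if not records:
        raise FormatError(f"{path}: no gene records")
    df = pd.DataFrame(records, columns=["gene", "chrom", "start", "end", "strand"])
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate gene id {dup.iloc[0]!r}")
    return GeneAnnotation(df.set_index("gene"))


def write_annotation_bed(annotation: GeneAnnotation, path: str | Path) -> None:
    t = annotation.table
    bed = pd.DataFrame(
        {
            "chrom": t["chrom"],
            "start": t["start"],
            "end": t["end"],
            "name": t.index,
            "score": 0,
            "strand": t["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_counts(counts_path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a gene × sample count TSV and its sample metadata TSV.

    The counts file has gene ids in the first column and sample ids in the
    header; the metadata file has columns ``sample_id``, ``sex`` and
    optionally ``stage``. Non-integer cells and metadata/column mismatches
    are rejected with messages naming the offender.
    """
    raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            gene = raw.index[vals.isna().to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{counts_path}: non-numeric count at gene {gene!r}, sample {col!r}"
            )
        frac = vals != np.floor(vals)
        if frac.any():
            gene = raw.index[frac.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{counts_path}: non-integer count at gene {gene!r}, sample {col!r}: "
                f"{vals[frac].iloc[0]!r}"
            )
        raw[col] = vals.astype(np.int64)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise FormatError(f"{metadata_path}: missing 'sample_id' column")
    meta = meta.set_index("sample_id")
    return CountMatrix(raw, meta)


def write_counts(cm: CountMatrix, counts_path: str | Path, metadata_path: str | Path) -> None:
    cm.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    cm.metadata.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# bedGraph coverage and TSS windows
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Parse 4-column bedGraph into per-chromosome (starts, ends, values).

    Intervals are sorted per chromosome; overlapping intervals are a format
    error (a position would have two coverage values).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if df.isna().any().any():
        raise FormatError(f"{path}: malformed bedGraph line")
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        vals = sub["value"].to_numpy(dtype=float)
        if (starts >= ends).any():
            raise FormatError(f"{path}: empty or inverted interval on {chrom}")
        if (starts[1:] < ends[:-1]).any():
            raise FormatError(f"{path}: overlapping intervals on {chrom}")
        out[chrom] = (starts, ends, vals)
    return out


def _window_mean(
    cov: tuple[np.ndarray, np.ndarray, np.ndarray], lo: int, hi: int
) -> float:
    """Overlap-weighted mean coverage over [lo, hi); uncovered bases count 0."""
    starts, ends, vals = cov
    i0 = int(np.searchsorted(ends, lo, side="right"))
    i1 = int(np.searchsorted(starts, hi, side="left"))
    if i1 <= i0:
        return 0.0
    s = np.maximum(starts[i0:i1], lo)
    e = np.minimum(ends[i0:i1], hi)
    total = float(np.sum((e - s) * vals[i0:i1]))
    return total / (hi - lo)


def average_over_tss(
    coverage_path: str | Path,
    annotation: GeneAnnotation,
    halfwidth: int = 1500,
    sex: str = "unknown",
) -> TSSWindowCounts:
    """Mean coverage over TSS ± ``halfwidth`` for every annotated gene.

    The TSS is the annotated start on the + strand and the annotated end on
    the − strand. Windows are truncated at position 0 and the mean is taken
    over the remaining (covered) width. Genes on chromosomes absent from the
    coverage file get 0 with a logged warning.
    """
    if len(annotation) == 0:
        raise DegenerateInputError("annotation is empty")
    if halfwidth <= 0:
        raise DegenerateInputError("halfwidth must be positive")
    cov = read_bedgraph(coverage_path)
    tss = annotation.tss
    chroms = annotation.table["chrom"]
    missing = sorted(set(chroms) - set(cov))
    if missing:
        logger.warning(
            "chromosomes absent from %s get zero coverage: %s", coverage_path, missing
        )
    values = np.zeros(len(annotation))
    for i, (gene, pos) in enumerate(tss.items()):
        chrom = chroms.iloc[i]
        if chrom not in cov:
            continue
        lo = max(int(pos) - halfwidth, 0)
        hi = int(pos) + halfwidth
        values[i] = _window_mean(cov[chrom], lo, hi)
    series = pd.Series(values, index=annotation.gene_ids, name="tss_mean")
    non_y = annotation.table["cls"] != "Y"
    return TSSWindowCounts(
        values=series,
        sex=sex,
        halfwidth=halfwidth,
        kind="average",
        total_excl_y=float(series[non_y].sum()),
    )


def write_bedgraph(
    intervals: Iterable[tuple[str, int, int, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Gene lists and pathway collections
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """Newline-delimited gene ids; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT pathway file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, genes")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate pathway id {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def pathway_sets_from_gmt(path: str | Path) -> Mapping[str, set[str]]:
    return read_gmt(path)
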