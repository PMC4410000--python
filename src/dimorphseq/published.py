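"""Reference published results bundled with the package.

The eight-cell-embryo dimorphism signature (69 genes with coordinates,
baseMean and log2FC male/female, defined at adjusted p < 0.1 and
|log2FC| > 0.5 from 6 male vs 6 female embryos) ships as a TSV so that
signature bookkeeping — chromosome-class composition, sex-chromosome
fraction — and cross-stage projections can be reproduced without access to
the raw sequencing data. The reported fetal/adult liver signature sizes and
fetal-to-adult conservation counts are kept as named constants for the
same arithmetic.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .containers import GeneAnnotation, chromosome_class
from .dimorphism import Signature

# Reported liver signature bookkeeping (gene counts as printed).
FETAL_LIVER_SIGNATURE_SIZE = 394
ADULT_LIVER_SIGNATURE_SIZE = 1488
# fetal-liver dimorphic genes also dimorphic in adult liver, by class
FETAL_TO_ADULT_CONSERVED = {
    "autosome": (264, 369),
    "X": (14, 21),
    "Y": (4, 4),
}


def load_eight_cell_signature() -> pd.DataFrame:
    """The bundled 69-gene eight-cell signature table.

    Columns: chrom, start, end, strand, base_mean,
    log2fc_male_over_female, cls (derived X / Y / autosome).
    """
    ref = resources.files("dimorphseq") / "data" / "eight_cell_signature.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col="gene")
    df["cls"] = df["chrom"].map(chromosome_class)
    return df


def eight_cell_signature() -> Signature:
    """The bundled signature as a :class:`~dimorphseq.dimorphism.Signature`
    (log2fc column aliased for projection use)."""
    df = load_eight_cell_signature().rename(
        columns={"log2fc_male_over_female": "log2fc"}
    )
    return Signature(df, padj_threshold=0.1, lfc_threshold=0.5)


def eight_cell_annotation() -> GeneAnnotation:
    """Gene coordinates of the bundled signature as an annotation."""
    df = load_eight_cell_signature()[["chrom", "start", "end", "strand"]]
    return GeneAnnotation(df)


def signature_class_counts() -> pd.Series:
    """Signature size by chromosome class (X / Y / autosome)."""
    return load_eight_cell_signature()["cls"].value_counts()


def sex_chromosome_fraction() -> float:
    """Fraction of the eight-cell signature on the sex chromosomes."""
    counts = signature_class_counts()
    return float((counts.get("X", 0) + counts.get("Y", 0)) / counts.sum())


def fetal_to_adult_conservation() -> dict[str, float]:
    """Per-class fraction of fetal-liver dimorphic genes conserved in adult
    liver, from the reported numerators/denominators."""
    return {cls: num / den for cls, (num, den) in FETAL_TO_ADULT_CONSERVED.items()}


def adult_fetal_signature_ratio() -> float:
    """Adult over fetal liver dimorphic-gene count ratio."""
    return ADULT_LIVER_SIGNATURE_SIZE / FETAL_LIVER_SIGNATURE_SIZE
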