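"""Projection of a fixed dimorphism signature onto other datasets.

A signature defined in one dataset (e.g. eight-cell embryos) is evaluated
in another (other developmental stages, tissues) by the per-gene log2 fold
change male/female of variance-stabilised counts — a mean difference rather
than a re-fit, because several comparison datasets have only 2–5 samples
per sex where GLM fits are unstable. Directional consistency between two
logFC tables is scored by same-sign counting with a chi-square
goodness-of-fit test against the 50:50 null, and X:autosome expression
ratios probe dosage-compensation (Ohno) hypotheses.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, GeneAnnotation
from .dimorphism import Signature, detect_expressed, size_factors, vst
from .exceptions import DegenerateInputError, DimorphSeqError


@dataclass
class ProjectionResult:
    """Per-signature-gene log2FC(male/female) in a target dataset.

    ``table`` columns: log2fc, conserved (|log2fc| > the conservation
    threshold), and cls when the signature carries classes. ``missing``
    lists signature genes absent from the target — never silently dropped.
    """

    table: pd.DataFrame
    missing: list[str]
    dataset: str
    conservation_threshold: float

    def class_summary(self) -> pd.DataFrame:
        if "cls" not in self.table.columns:
            raise DimorphSeqError("projection has no chromosome classes")
        groups = self.table.groupby("cls")["log2fc"]
        return pd.DataFrame(
            {
                "n": groups.size(),
                "median": groups.median(),
                "q25": groups.quantile(0.25),
                "q75": groups.quantile(0.75),
            }
        )


@dataclass
class ConsistencyResult:
    """Sign agreement of two per-gene logFC tables vs the 50:50 null."""

    n_same_sign: int
    n_opposite_sign: int
    chi_square: float
    pvalue: float
    floor: float

    @property
    def n_compared(self) -> int:
        return self.n_same_sign + self.n_opposite_sign

    @property
    def fraction_consistent(self) -> float:
        return self.n_same_sign / self.n_compared


def project_logfc(
    signature: Signature,
    target: CountMatrix,
    dataset: str = "target",
    conservation_threshold: float = 0.5,
) -> ProjectionResult:
    """log2FC(male/female) of each signature gene in ``target``.

    Computed as mean male minus mean female of the variance-stabilised
    (log2(normalised + 1)) counts; the VST pseudocount keeps zero-count
    groups finite. Genes with |log2fc| above ``conservation_threshold`` are
    flagged as conserved dimorphism.
    """
    males = target.samples_of_sex("male")
    females = target.samples_of_sex("female")
    if not males or not females:
        raise DimorphSeqError("target dataset must contain both sexes")
    present = [g for g in signature.gene_ids if g in target.counts.index]
    missing = [g for g in signature.gene_ids if g not in target.counts.index]
    if not present:
        raise DimorphSeqError("no signature gene is present in the target dataset")
    v = vst(target)
    lfc = v.loc[present, males].mean(axis=1) - v.loc[present, females].mean(axis=1)
    table = pd.DataFrame({"log2fc": lfc})
    table["conserved"] = table["log2fc"].abs() > conservation_threshold
    if "cls" in signature.table.columns:
        table["cls"] = signature.table["cls"].reindex(present)
    return ProjectionResult(table, missing, dataset, conservation_threshold)


def directional_consistency(
    lfc_a: pd.Series, lfc_b: pd.Series, floor: float = 0.0
) -> ConsistencyResult:
    """Same-sign counting over shared genes, chi-square vs 50:50.

    Genes with |logFC| <= ``floor`` in either table (and exact zeros, which
    carry no sign) are excluded; the statistic is the 1-df goodness-of-fit
    chi-square of (n_same, n_opposite) against equal proportions, without
    continuity correction.
    """
    shared = lfc_a.index.intersection(lfc_b.index)
    a = lfc_a.loc[shared].astype(float)
    b = lfc_b.loc[shared].astype(float)
    keep = (a.abs() > floor) & (b.abs() > floor)
    a, b = a[keep], b[keep]
    n = len(a)
    if n == 0:
        raise DegenerateInputError("no shared genes above the dimorphism floor")
    same = int((np.sign(a) == np.sign(b)).sum())
    opp = n - same
    expected = n / 2.0
    chi2 = (same - expected) ** 2 / expected + (opp - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return ConsistencyResult(same, opp, float(chi2), p, floor)


def correlate_logfc(
    lfc_a: pd.Series, lfc_b: pd.Series, method: str = "spearman"
) -> tuple[float, float]:
    """Correlation of two per-gene logFC tables on their shared genes."""
    shared = lfc_a.index.intersection(lfc_b.index)
    if len(shared) < 3:
        raise DimorphSeqError(f"need >= 3 shared genes, have {len(shared)}")
    a = lfc_a.loc[shared].to_numpy(dtype=float)
    b = lfc_b.loc[shared].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("correlation undefined for a constant logFC vector")
    if method == "spearman":
        r, p = stats.spearmanr(a, b)
    elif method == "pearson":
        r, p = stats.pearsonr(a, b)
    else:
        raise DimorphSeqError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def x_autosome_ratio(
    counts: CountMatrix,
    annotation: GeneAnnotation,
    sex: str,
    detect_rule: str = "all_samples_nonzero",
) -> float:
    """Mean X-linked over mean autosomal normalised expression in one sex.

    Both means are over expressed genes only (default detection rule); Y
    genes never enter either term. A ratio near 2 in both sexes is the
    doubled-active-X (Ohno) pattern; near 1 means no X up-regulation.
    """
    samples = counts.samples_of_sex(sex)
    if not samples:
        raise DimorphSeqError(f"no {sex} samples in the dataset")
    expressed = set(detect_expressed(counts, detect_rule))
    cls = annotation.table["cls"]
    x_genes = [g for g in expressed if cls.get(g) == "X"]
    auto_genes = [g for g in expressed if cls.get(g) == "autosome"]
    if not x_genes or not auto_genes:
        raise DegenerateInputError(
            "need expressed genes in both the X and autosomal classes"
        )
    sf = size_factors(counts)
    normed = counts.counts[samples] / sf[samples]
    x_mean = float(normed.loc[x_genes].to_numpy().mean())
    auto_mean = float(normed.loc[auto_genes].to_numpy().mean())
    return x_mean / auto_mean
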