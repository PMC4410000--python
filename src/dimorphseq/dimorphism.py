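"""Sexually dimorphic expression calling from a count matrix.

The model is the standard bulk RNA-seq two-group design: per-sample depth is
normalised with median-of-ratios size factors, each gene's counts are
modelled as negative binomial with variance mu + alpha * mu**2, and the sex
effect is tested with a Wald test on the sex coefficient of a log-link NB
GLM (log2 fold change reported male over female). P-values are adjusted with
Benjamini-Hochberg over the tested (expression-filtered) genes, and a
signature is the thresholded subset padj < 0.1 and |log2FC| > 0.5.

Gene-wise dispersions are method-of-moments estimates moderated toward a
fitted mean-dispersion trend; this is deliberately simpler than the
empirical-Bayes shrinkage of full differential-expression frameworks and no
numeric parity with them is claimed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import CountMatrix, GeneAnnotation
from .exceptions import DegenerateInputError, DimorphSeqError

_LN2 = np.log(2.0)
_MIN_DISPERSION = 1e-8


# ---------------------------------------------------------------------------
# Normalisation and filtering
# ---------------------------------------------------------------------------

def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with non-zero counts in every sample enter the reference
    (their geometric mean); each sample's factor is the median over those
    genes of count / reference.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise DegenerateInputError(
            "no gene is non-zero in all samples; median-of-ratios is undefined "
            "(consider library-size normalisation)"
        )
    ref = np.exp(np.mean(np.log(arr[all_nonzero]), axis=1))
    ratios = arr[all_nonzero] / ref[:, None]
    sf = np.median(ratios, axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=df.columns, name="size_factor")


def library_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Total-count factors rescaled to geometric mean 1 (sparse-data fallback)."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    tot = df.sum(axis=0).astype(float)
    if (tot <= 0).any():
        raise DegenerateInputError("a sample has zero total counts")
    sf = tot / np.exp(np.mean(np.log(tot)))
    return sf.rename("size_factor")


def detect_expressed(
    counts: CountMatrix, rule: str = "all_samples_nonzero"
) -> list[str]:
    """Genes passing the expression-detection rule.

    Rules: ``all_samples_nonzero`` (default; a gene must have a non-zero
    count in every sample) or ``mean_ge:<t>`` (mean of size-factor-normalised
    counts >= t, inclusive).
    """
    if rule == "all_samples_nonzero":
        mask = (counts.counts > 0).all(axis=1)
    elif rule.startswith("mean_ge:"):
        try:
            threshold = float(rule.split(":", 1)[1])
        except ValueError as exc:
            raise DimorphSeqError(f"bad threshold in rule {rule!r}") from exc
        sf = size_factors(counts)
        normed = counts.counts / sf
        mask = normed.mean(axis=1) >= threshold
    else:
        raise DimorphSeqError(f"unknown detection rule {rule!r}")
    return list(counts.counts.index[mask])


def vst(counts: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Variance-stabilising transform used for plotting and projection:
    log2(normalised count + 1)."""
    if factors is None:
        factors = size_factors(counts)
    return np.log2(counts.counts / factors + 1.0)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, cumulative minimum)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

def _moments_dispersion(
    normed: np.ndarray, groups: list[np.ndarray]
) -> np.ndarray:
    """Method-of-moments gene-wise dispersion from normalised counts.

    Solves var = mu + alpha * mu**2 within each sex group and pools the two
    estimates. Normalised counts are treated as NB directly, which keeps
    fold-change estimates exactly invariant to per-sample depth scaling; for
    size factors with geometric mean 1 the resulting dispersion bias is
    O((mean(1/sf) - 1)/mu), negligible at the depth structure modelled here.
    Floored at 1e-8.
    """
    num = np.zeros(normed.shape[0])
    den = np.zeros(normed.shape[0])
    for idx in groups:
        if idx.size < 2:
            continue
        sub = normed[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = idx.size - 1
        num += w * (v - m)
        den += w * np.square(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.maximum(alpha, _MIN_DISPERSION)


def _dispersion_trend(mean_: np.ndarray, alpha_raw: np.ndarray):
    """Fit alpha ~ a0 + a1 / mean over informative genes (non-negative ls)."""
    ok = (alpha_raw > 10 * _MIN_DISPERSION) & (mean_ > 0)
    if ok.sum() < 10:
        med = float(np.median(alpha_raw[alpha_raw > _MIN_DISPERSION])) if (
            alpha_raw > _MIN_DISPERSION
        ).any() else 0.01
        return lambda mu: np.full_like(np.asarray(mu, dtype=float), med)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mean_[ok]])
    y = alpha_raw[ok]
    # one reweighting pass to blunt the influence of outlying genes
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = np.abs(y - X @ coef)
    scale = np.median(resid) + 1e-12
    w = 1.0 / (1.0 + (resid / (3 * scale)) ** 2)
    coef, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
    coef = np.maximum(coef, 0.0)
    if coef.sum() == 0:
        med = float(np.median(y))
        return lambda mu: np.full_like(np.asarray(mu, dtype=float), med)

    def trend(mu):
        mu = np.maximum(np.asarray(mu, dtype=float), 1e-8)
        return coef[0] + coef[1] / mu

    return trend


# ---------------------------------------------------------------------------
# Model / results
# ---------------------------------------------------------------------------

@dataclass
class Signature:
    """Thresholded dimorphism table: padj < padj_threshold and
    |log2fc| > lfc_threshold (both strict)."""

    table: pd.DataFrame
    padj_threshold: float
    lfc_threshold: float

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def counts_by_class(self) -> pd.Series:
        if "cls" not in self.table.columns:
            raise DimorphSeqError("signature has no chromosome classes (no annotation given)")
        return self.table["cls"].value_counts()

    def genes_of_class(self, cls: str) -> list[str]:
        if "cls" not in self.table.columns:
            raise DimorphSeqError("signature has no chromosome classes (no annotation given)")
        return list(self.table.index[self.table["cls"] == cls])


class DimorphismModel:
    """Two-group negative-binomial model of sex-dimorphic expression.

    Parameters
    ----------
    counts : CountMatrix
        Counts with metadata whose ``sex`` column labels every sample
        ``male`` or ``female`` (run sex calling first if unknown).
    annotation : GeneAnnotation, optional
        When given, result tables carry the chromosome class of each gene.
    detect_rule : str
        Expression filter; genes failing it are reported untested.
    """

    def __init__(
        self,
        counts: CountMatrix,
        annotation: GeneAnnotation | None = None,
        detect_rule: str = "all_samples_nonzero",
    ) -> None:
        sex = counts.sex
        if (sex == "unknown").any():
            raise DimorphSeqError(
                "samples with unknown sex; run sex calling before testing"
            )
        for label in ("male", "female"):
            if (sex == label).sum() < 2:
                raise DimorphSeqError(f"need >= 2 {label} samples, have {(sex == label).sum()}")
        self.counts = counts
        self.annotation = annotation
        self.detect_rule = detect_rule

    @classmethod
    def from_files(
        cls, counts_path, metadata_path, annotation_path=None, **kwargs
    ) -> "DimorphismModel":
        from . import io

        cm = io.read_counts(counts_path, metadata_path)
        ann = io.read_annotation(annotation_path) if annotation_path else None
        return cls(cm, annotation=ann, **kwargs)

    def fit(self) -> "DimorphismResults":
        cm = self.counts
        sf = size_factors(cm)
        detected = set(detect_expressed(cm, self.detect_rule))

        genes = cm.counts.index
        arr = cm.counts.to_numpy(dtype=float)
        sfv = sf.to_numpy()
        normed = arr / sfv[None, :]
        is_male = (cm.sex == "male").to_numpy()
        groups = [np.flatnonzero(is_male), np.flatnonzero(~is_male)]
        xi = float(np.mean(1.0 / sfv))

        base_mean = normed.mean(axis=1)
        tested_mask = np.asarray(genes.isin(detected)) & (base_mean > 0)

        alpha_raw = _moments_dispersion(normed, groups)
        trend = _dispersion_trend(base_mean[tested_mask], alpha_raw[tested_mask])
        alpha = np.where(
            base_mean > 0,
            np.maximum(0.5 * alpha_raw + 0.5 * trend(np.maximum(base_mean, 1e-8)), _MIN_DISPERSION),
            _MIN_DISPERSION,
        )

        design = np.column_stack([np.ones(arr.shape[1]), is_male.astype(float)])
        offset = np.log(sfv)
        log2fc = np.full(len(genes), np.nan)
        se = np.full(len(genes), np.nan)
        pvalue = np.full(len(genes), np.nan)
        # estimates for every non-empty gene; padj only over the tested ones
        for i in np.flatnonzero(base_mean > 0):
            log2fc[i], se[i], pvalue[i] = _wald_one_gene(
                arr[i], design, offset, alpha[i], normed[i], groups, xi
            )

        padj = np.full(len(genes), np.nan)
        idx = np.flatnonzero(tested_mask & np.isfinite(pvalue))
        padj[idx] = bh_adjust(pvalue[idx])

        table = pd.DataFrame(
            {
                "base_mean": base_mean,
                "log2fc": log2fc,
                "se": se,
                "pvalue": pvalue,
                "padj": padj,
                "tested": tested_mask & np.isfinite(pvalue),
            },
            index=genes,
        )
        if self.annotation is not None:
            table["cls"] = self.annotation.table["cls"].reindex(genes)
        return DimorphismResults(
            table=table,
            size_factors_=sf,
            dispersions=pd.Series(alpha, index=genes, name="dispersion"),
            model=self,
        )


def _wald_one_gene(y, design, offset, alpha, normed_row, groups, xi):
    """Wald test for the sex coefficient of one gene's NB GLM.

    Returns (log2fc male/female, se of log2fc, two-sided p). When one sex
    group is entirely zero the GLM separates; a moment-based Wald on
    pseudocounted group means is used instead.
    """
    male_idx, female_idx = groups
    if y[male_idx].sum() == 0 or y[female_idx].sum() == 0:
        return _moment_wald(normed_row, groups, alpha, xi)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fam = sm.families.NegativeBinomial(alpha=max(alpha, 1e-6))
            res = sm.GLM(y, design, family=fam, offset=offset).fit(maxiter=100)
        coef = res.params[1]
        bse = res.bse[1]
        if not (np.isfinite(coef) and np.isfinite(bse)) or bse <= 0:
            return _moment_wald(normed_row, groups, alpha, xi)
        z = coef / bse
        p = 2.0 * stats.norm.sf(abs(z))
        return coef / _LN2, bse / _LN2, p
    except Exception:
        return _moment_wald(normed_row, groups, alpha, xi)


def _moment_wald(normed_row, groups, alpha, xi, pseudocount=0.5):
    male_idx, female_idx = groups
    mm = normed_row[male_idx].mean() + pseudocount
    mf = normed_row[female_idx].mean() + pseudocount
    lfc = np.log2(mm / mf)
    var_m = (mm * xi + alpha * mm**2) / (male_idx.size * mm**2)
    var_f = (mf * xi + alpha * mf**2) / (female_idx.size * mf**2)
    se_ln = np.sqrt(var_m + var_f)
    z = (np.log(mm) - np.log(mf)) / se_ln
    p = 2.0 * stats.norm.sf(abs(z))
    return lfc, se_ln / _LN2, p


@dataclass
class DimorphismResults:
    """Per-gene dimorphism table with the fitted nuisance parameters.

    ``table`` columns: base_mean (mean normalised count over all samples),
    log2fc (male over female), se, pvalue, padj (BH over tested genes),
    tested, and cls when an annotation was supplied.
    """

    table: pd.DataFrame
    size_factors_: pd.Series
    dispersions: pd.Series
    model: DimorphismModel = field(repr=False)

    @property
    def n_tested(self) -> int:
        return int(self.table["tested"].sum())

    def signature(
        self, padj_threshold: float = 0.1, lfc_threshold: float = 0.5
    ) -> Signature:
        return define_signature(self.table, padj_threshold, lfc_threshold)

    def summary(self) -> str:
        t = self.table
        sig = self.signature()
        lines = [
            "Dimorphism model (NB GLM, Wald test on sex, log2FC male/female)",
            f"  genes: {len(t)}  tested: {self.n_tested}",
            f"  signature (padj<0.1, |log2FC|>0.5): {len(sig)} genes",
        ]
        if "cls" in t.columns and len(sig):
            by = sig.counts_by_class()
            lines.append(
                "  by class: " + ", ".join(f"{k}={v}" for k, v in by.items())
            )
        top = t[t["tested"]].nsmallest(10, "padj")
        lines.append(top.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def to_table1_style(self, annotation: GeneAnnotation | None = None) -> pd.DataFrame:
        """Export with annotation columns (Gene name, CHR, Start, End, Strand,
        baseMean, log2FoldChange, pvalue, padj)."""
        ann = annotation or self.model.annotation
        t = self.table
        out = pd.DataFrame(index=t.index)
        if ann is not None:
            a = ann.table.reindex(t.index)
            out["CHR"] = a["chrom"]
            out["Start"] = a["start"]
            out["End"] = a["end"]
            out["Strand"] = a["strand"]
        out["baseMean"] = t["base_mean"]
        out["log2FoldChange"] = t["log2fc"]
        out["pvalue"] = t["pvalue"]
        out["padj"] = t["padj"]
        return out.rename_axis("Gene name")


def test_dimorphism(
    counts: CountMatrix,
    sex: pd.Series | None = None,
    annotation: GeneAnnotation | None = None,
    detect_rule: str = "all_samples_nonzero",
) -> pd.DataFrame:
    """Functional wrapper: fit the two-group NB model and return the table."""
    if sex is not None:
        counts = counts.with_sex(sex)
    return DimorphismModel(counts, annotation=annotation, detect_rule=detect_rule).fit().table


def define_signature(
    table: pd.DataFrame, padj_threshold: float = 0.1, lfc_threshold: float = 0.5
) -> Signature:
    """Threshold a dimorphism table into a signature (strict inequalities)."""
    if padj_threshold <= 0 or lfc_threshold <= 0:
        raise DimorphSeqError("signature thresholds must be positive")
    if "padj" not in table.columns:
        raise DimorphSeqError("table has no padj column")
    keep = (table["padj"] < padj_threshold) & (table["log2fc"].abs() > lfc_threshold)
    keep = keep.fillna(False)
    return Signature(table[keep].copy(), padj_threshold, lfc_threshold)
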