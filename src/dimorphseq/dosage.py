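"""X-chromosome dosage model for sex-comparative ChIP-seq TSS enrichment.

Females carry two X chromosomes, males one, so raw female ChIP signal on
chrX is expected to be about twice the male signal even without any
sex-biased chromatin state. The model scales the male per-gene TSS read
density to the female expectation under pure 2x dosage:

    S_i = 2 * N_i / (N_total + N_x)

where N_i is the (replicate-averaged) male read count in the TSS window of
X-linked gene i, N_total the male total over all non-Y genes and N_x the
male total over chrX genes — doubling chrX reads both in the numerator and
in the library total. The observed female density is

    A_i = N_i_female / N_ftotal

with N_ftotal the female non-Y total. Genes matching pure dosage fall on
A_i = S_i; a gene set's female fold enrichment beyond dosage is

    FE_female = sum(A_i, i in set) / sum(S_i, i in set)

(read-weighted, robust to near-zero per-gene densities), tested by
permuting same-size sets from the fitted X-gene background.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import GeneAnnotation, TSSWindowCounts
from .exceptions import DegenerateInputError, DimorphSeqError, UnknownGeneError


@dataclass
class FoldEnrichmentResult:
    """Female fold enrichment of a gene set with its permutation null."""

    set_id: str
    fe_female: float
    pvalue: float
    n_permutations: int
    seed: int | None
    set_size: int
    background_size: int
    alternative: str

    def __str__(self) -> str:
        return (
            f"{self.set_id}: FE_female = {self.fe_female:.3f}, "
            f"p = {self.pvalue:.4g} ({self.n_permutations} permutations, "
            f"{self.alternative}, set {self.set_size} / background {self.background_size})"
        )


def _average_tracks(tracks: TSSWindowCounts | Sequence[TSSWindowCounts]) -> TSSWindowCounts:
    if isinstance(tracks, TSSWindowCounts):
        return tracks
    tracks = list(tracks)
    if not tracks:
        raise DimorphSeqError("no replicate tracks given")
    first = tracks[0]
    values = first.values.copy()
    for t in tracks[1:]:
        if not t.values.index.equals(first.values.index):
            raise DimorphSeqError("replicate tracks cover different gene sets")
        if t.halfwidth != first.halfwidth or t.kind != first.kind:
            raise DimorphSeqError("replicate tracks have mismatched window definitions")
        values = values + t.values
    values = values / len(tracks)
    return TSSWindowCounts(
        values=values,
        sex=first.sex,
        halfwidth=first.halfwidth,
        kind=first.kind,
        total_excl_y=float(np.nan),
    )


class DosageModel:
    """Fit the 2x-dosage expectation for female X-linked TSS signal.

    Parameters
    ----------
    male, female : TSSWindowCounts or sequence of replicates
        Per-gene TSS window signal per sex; replicates are averaged
        gene-wise before any total is formed.
    annotation : GeneAnnotation
        Supplies chromosome classes; chrY genes are removed from every
        total and X genes define the modelled set.
    """

    def __init__(
        self,
        male: TSSWindowCounts | Sequence[TSSWindowCounts],
        female: TSSWindowCounts | Sequence[TSSWindowCounts],
        annotation: GeneAnnotation,
    ) -> None:
        self.male = _average_tracks(male)
        self.female = _average_tracks(female)
        self.annotation = annotation
        for track in (self.male, self.female):
            missing = annotation.gene_ids.difference(track.values.index)
            if len(missing):
                raise DimorphSeqError(
                    f"track is missing annotated genes, e.g. {missing[0]!r}"
                )

    def fit(self) -> "DosageResults":
        ann = self.annotation.table
        non_y = ann.index[ann["cls"] != "Y"]
        x_genes = ann.index[ann["cls"] == "X"]
        if len(x_genes) == 0:
            raise DegenerateInputError("annotation has no X genes to model")

        male_v = self.male.values.reindex(ann.index)
        female_v = self.female.values.reindex(ann.index)
        n_total = float(male_v[non_y].sum())
        n_x = float(male_v[x_genes].sum())
        n_ftotal = float(female_v[non_y].sum())
        if n_total + n_x == 0:
            raise DegenerateInputError("male track has zero reads outside chrY")
        if n_ftotal == 0:
            raise DegenerateInputError("female track has zero reads outside chrY")

        n_i = male_v[x_genes]
        n_i_f = female_v[x_genes]
        table = pd.DataFrame(
            {
                "n_male": n_i,
                "s": 2.0 * n_i / (n_total + n_x),
                "n_female": n_i_f,
                "a": n_i_f / n_ftotal,
            },
            index=x_genes,
        )
        table["zero_signal"] = (table["n_male"] == 0) & (table["n_female"] == 0)
        return DosageResults(
            table=table,
            n_total=n_total,
            n_x=n_x,
            n_ftotal=n_ftotal,
            halfwidth=self.male.halfwidth,
            kind=self.male.kind,
            model=self,
        )


@dataclass
class DosageResults:
    """Per-X-gene scaled male density S and observed female density A.

    ``table`` columns: n_male, s, n_female, a, zero_signal. The library
    totals that define the densities are kept alongside.
    """

    table: pd.DataFrame
    n_total: float
    n_x: float
    n_ftotal: float
    halfwidth: int
    kind: str
    model: DosageModel = field(repr=False)

    @property
    def background(self) -> list[str]:
        """Fitted X genes with non-zero scaled male density (permutable)."""
        return list(self.table.index[self.table["s"] > 0])

    def _check_set(self, gene_set: Iterable[str]) -> list[str]:
        genes = list(dict.fromkeys(gene_set))
        if not genes:
            raise DimorphSeqError("gene set is empty")
        unknown = [g for g in genes if g not in self.table.index]
        if unknown:
            raise UnknownGeneError(f"gene {unknown[0]!r} is not a fitted X gene")
        return genes

    def fold_enrichment(self, gene_set: Iterable[str]) -> float:
        """FE_female = sum(A_i) / sum(S_i) over the set. > 1 means female
        signal above the 2x-dosage expectation, < 1 below it."""
        genes = self._check_set(gene_set)
        s_sum = float(self.table.loc[genes, "s"].sum())
        a_sum = float(self.table.loc[genes, "a"].sum())
        if s_sum == 0:
            raise DegenerateInputError("set has zero scaled male density; FE undefined")
        return a_sum / s_sum

    def permutation_test(
        self,
        gene_set: Iterable[str],
        n_permutations: int = 10_000,
        seed: int | None = None,
        alternative: str = "two_sided",
        set_id: str = "set",
    ) -> FoldEnrichmentResult:
        """Permutation p-value of the set's FE against same-size random
        X-gene sets: p = (b + 1) / (n + 1) with b the number of null FEs at
        least as extreme (two-sided on |log FE|)."""
        if alternative not in ("two_sided", "greater", "less"):
            raise DimorphSeqError(f"unknown alternative {alternative!r}")
        genes = self._check_set(gene_set)
        fe_obs = self.fold_enrichment(genes)
        bg = self.background
        k = len([g for g in genes if g in bg]) or len(genes)
        if len(bg) <= len(genes):
            raise DegenerateInputError(
                "permutation null is degenerate: the set covers the whole background"
            )
        a = self.table.loc[bg, "a"].to_numpy()
        s = self.table.loc[bg, "s"].to_numpy()
        rng = np.random.default_rng(seed)
        m = len(bg)
        null = np.empty(n_permutations)
        chunk = max(1, min(n_permutations, int(2e6 / max(m, 1)) + 1))
        done = 0
        while done < n_permutations:
            c = min(chunk, n_permutations - done)
            keys = rng.random((c, m))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            null[done : done + c] = a[idx].sum(axis=1) / s[idx].sum(axis=1)
            done += c
        if alternative == "greater":
            b = int((null >= fe_obs).sum())
        elif alternative == "less":
            b = int((null <= fe_obs).sum())
        else:
            b = int((np.abs(np.log(null)) >= abs(np.log(fe_obs))).sum())
        p = (b + 1) / (n_permutations + 1)
        return FoldEnrichmentResult(
            set_id=set_id,
            fe_female=fe_obs,
            pvalue=p,
            n_permutations=n_permutations,
            seed=seed,
            set_size=len(genes),
            background_size=m,
            alternative=alternative,
        )

    def summary(self) -> str:
        t = self.table
        return "\n".join(
            [
                "X-dosage model for sex-comparative TSS enrichment",
                f"  X genes fitted: {len(t)} ({int(t['zero_signal'].sum())} with zero signal)",
                f"  totals: N_total(male, non-Y) = {self.n_total:.1f}, "
                f"N_x(male, chrX) = {self.n_x:.1f}, N_ftotal(female, non-Y) = {self.n_ftotal:.1f}",
                f"  window: TSS +/- {self.halfwidth} bp ({self.kind} signal)",
                f"  genome-wide FE over all fitted X genes: "
                f"{t['a'].sum() / max(t['s'].sum(), 1e-300):.3f}",
            ]
        )


def fit_dosage_model(
    male: TSSWindowCounts | Sequence[TSSWindowCounts],
    female: TSSWindowCounts | Sequence[TSSWindowCounts],
    annotation: GeneAnnotation,
) -> DosageResults:
    """Functional wrapper around :class:`DosageModel`."""
    return DosageModel(male, female, annotation).fit()
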