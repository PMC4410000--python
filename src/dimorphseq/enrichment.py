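"""Gene-set overlap statistics against explicit backgrounds.

Two complementary tests: (1) fold enrichment of the overlap of two gene
sets over its expectation |A|*|B|/|background| with a permutation p-value
(redrawing set A from the background), used e.g. for fetal-vs-adult liver
signature overlap and growth-hormone-responsive gene enrichment; (2)
one-sided hypergeometric pathway enrichment with Bonferroni correction,
used for pathway analyses with deliberately chosen custom backgrounds
(e.g. detected X-linked genes only). The background is always supplied by
the caller, never inferred.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, DimorphSeqError, UnknownGeneError


@dataclass
class OverlapResult:
    """Observed vs expected overlap of two gene sets in a background."""

    n_a: int
    n_b: int
    n_overlap: int
    n_background: int
    fold_enrichment: float
    pvalue: float
    hypergeometric_pvalue: float
    n_permutations: int
    seed: int | None

    @property
    def expected_overlap(self) -> float:
        return self.n_a * self.n_b / self.n_background

    def __str__(self) -> str:
        return (
            f"overlap {self.n_overlap}/{min(self.n_a, self.n_b)} "
            f"(|A|={self.n_a}, |B|={self.n_b}, background={self.n_background}): "
            f"{self.fold_enrichment:.2f}x enrichment, permutation p = {self.pvalue:.4g}, "
            f"hypergeometric p = {self.hypergeometric_pvalue:.4g}"
        )


def _validate_subset(name: str, members: set, background: set) -> None:
    outside = members - background
    if outside:
        raise UnknownGeneError(
            f"{name} contains {sorted(outside)[0]!r}, which is not in the background"
        )


def overlap_fold_enrichment(
    set_a: Iterable[str],
    set_b: Iterable[str],
    background: Iterable[str],
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> OverlapResult:
    """Fold enrichment of |A ∩ B| over |A||B|/|background|.

    The permutation null redraws A uniformly from the background and
    recounts the overlap; p = (b + 1)/(n + 1), upper tail. The one-sided
    hypergeometric p is reported alongside since either may be wanted.
    """
    bg = list(dict.fromkeys(background))
    bg_set = set(bg)
    if not bg:
        raise DegenerateInputError("background is empty")
    a = set(set_a)
    b = set(set_b)
    _validate_subset("set A", a, bg_set)
    _validate_subset("set B", b, bg_set)
    if not a or not b:
        raise DegenerateInputError("expected overlap is zero for an empty set; FE undefined")
    observed = len(a & b)
    expected = len(a) * len(b) / len(bg)
    fe = observed / expected

    in_b = np.fromiter((g in b for g in bg), dtype=bool, count=len(bg))
    rng = np.random.default_rng(seed)
    k = len(a)
    m = len(bg)
    null = np.empty(n_permutations, dtype=np.int64)
    chunk = max(1, min(n_permutations, int(2e6 / max(m, 1)) + 1))
    done = 0
    while done < n_permutations:
        c = min(chunk, n_permutations - done)
        keys = rng.random((c, m))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null[done : done + c] = in_b[idx].sum(axis=1)
        done += c
    p_perm = (int((null >= observed).sum()) + 1) / (n_permutations + 1)
    p_hyper = float(stats.hypergeom.sf(observed - 1, m, len(b), len(a)))
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_overlap=observed,
        n_background=m,
        fold_enrichment=fe,
        pvalue=p_perm,
        hypergeometric_pvalue=p_hyper,
        n_permutations=n_permutations,
        seed=seed,
    )


def pathway_enrichment(
    query: Iterable[str],
    pathway_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a query set in each pathway.

    Pathways are intersected with the background before testing; pathways
    disjoint from the background are excluded from testing and from the
    Bonferroni denominator. Rows sorted by adjusted p.
    """
    bg = set(background)
    if not bg:
        raise DegenerateInputError("background is empty")
    q = set(query)
    _validate_subset("query", q, bg)
    rows = []
    tested = {
        pid: set(genes) & bg
        for pid, genes in pathway_sets.items()
        if set(genes) & bg
    }
    if not tested:
        raise DimorphSeqError("no pathway intersects the background")
    n_tests = len(tested)
    for pid, members in tested.items():
        k = len(q & members)
        big_k = len(members)
        n = len(q)
        big_n = len(bg)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {
                "pathway": pid,
                "k_overlap": k,
                "K_pathway": big_k,
                "n_query": n,
                "N_background": big_n,
                "pvalue": p,
                "padj_bonferroni": min(1.0, p * n_tests),
            }
        )
    df = pd.DataFrame(rows).set_index("pathway")
    return df.sort_values(["padj_bonferroni", "pvalue"])
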