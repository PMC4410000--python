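"""Sample sex assignment from marker-gene expression.

Each sample is a point in the 2-D space of log-normalised expression of a
female marker (Xist, X-linked, female-specific) and a male marker (Eif2s3y,
Y-linked, male-specific). Samples are split into two groups with a
deterministic 2-centre assignment — initialised from the farthest pair of
samples, one refinement pass — and the group with the higher mean
male-marker expression is labelled male. No randomness is involved, so
calls are reproducible and order-invariant.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .dimorphism import library_size_factors, size_factors
from .exceptions import DegenerateInputError, DimorphSeqError, UnknownGeneError


def _normalised_marker_matrix(
    counts: CountMatrix, markers: list[str]
) -> pd.DataFrame:
    try:
        sf = size_factors(counts)
    except DegenerateInputError:
        # sparse libraries (e.g. few-cell embryos) may share no always-on gene
        sf = library_size_factors(counts)
    sub = counts.counts.loc[markers]
    return np.log2(sub / sf + 1.0)


def call_sex(
    counts: CountMatrix,
    female_marker: str = "Xist",
    male_marker: str = "Eif2s3y",
) -> pd.DataFrame:
    """Call the sex of every sample from the two marker genes.

    Returns a DataFrame indexed by sample id with columns ``sex``,
    ``female_marker`` and ``male_marker`` (log2 normalised expression), and
    ``margin`` — the difference between the distance to the other group's
    centre and to the own group's centre (>= 0 after refinement; small
    margins flag ambiguous samples).
    """
    for marker in (female_marker, male_marker):
        if marker not in counts.counts.index:
            raise UnknownGeneError(f"marker gene {marker!r} not in count matrix")
    if counts.n_samples < 2:
        raise DimorphSeqError("sex calling needs at least 2 samples")

    logm = _normalised_marker_matrix(counts, [female_marker, male_marker])
    pts = logm.to_numpy().T  # samples x 2
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    if d2.max() == 0:
        raise DegenerateInputError("all samples have identical marker expression")

    # farthest pair initialises the two centres (ties: first in sample order)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    centres = pts[[min(i, j), max(i, j)]]
    assign = np.argmin(
        np.sum((pts[:, None, :] - centres[None, :, :]) ** 2, axis=-1), axis=1
    )
    # single refinement pass
    for g in (0, 1):
        if (assign == g).any():
            centres[g] = pts[assign == g].mean(axis=0)
    dists = np.sqrt(np.sum((pts[:, None, :] - centres[None, :, :]) ** 2, axis=-1))
    assign = np.argmin(dists, axis=1)

    male_mean = [pts[assign == g, 1].mean() if (assign == g).any() else -np.inf for g in (0, 1)]
    male_group = int(np.argmax(male_mean))
    sex = np.where(assign == male_group, "male", "female")
    margin = np.abs(dists[:, 0] - dists[:, 1])

    return pd.DataFrame(
        {
            "sex": sex,
            "female_marker": pts[:, 0],
            "male_marker": pts[:, 1],
            "margin": margin,
        },
        index=counts.sample_ids,
    )


def apply_sex_calls(counts: CountMatrix, calls: pd.DataFrame, force: bool = False) -> CountMatrix:
    """Fill metadata sexes from calls; refuses to overwrite known sexes
    unless ``force``."""
    known = counts.metadata["sex"] != "unknown"
    if known.any() and not force:
        clash = counts.metadata.loc[known, "sex"] != calls.loc[known[known].index, "sex"]
        if clash.any():
            raise DimorphSeqError(
                "sex calls disagree with existing metadata for samples "
                f"{list(clash[clash].index)}; pass force=True to overwrite"
            )
    return counts.with_sex(calls["sex"])
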