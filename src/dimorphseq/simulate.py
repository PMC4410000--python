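"""Synthetic data with the statistical structure the analysis assumes.

The generator inverts the analysis model: negative-binomial counts with
gene-wise dispersion (variance mu + alpha*mu^2), log-normal per-sample
library sizes, a female 2x dosage shift on X-linked genes, Y-linked genes
silent in females, the Xist/Eif2s3y sex markers at their reference
eight-cell-embryo effect sizes, and planted sign-balanced autosomal
dimorphic effects. TSS window counts are Poisson about per-gene expectations
whose female X signal is a tunable multiple of the male signal.

Ground truth records every planted effect so recovery can be scored.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import CountMatrix, GeneAnnotation, TSSWindowCounts
from .exceptions import InvalidConfigError, UnknownGeneError

FEMALE_MARKER = "Xist"
MALE_MARKER = "Eif2s3y"

# reference eight-cell-embryo marker effect sizes, log2(male/female)
XIST_LOG2FC = -9.01
EIF2S3Y_LOG2FC = 5.94
_MARKER_BASE_MEAN = {FEMALE_MARKER: 275.0, MALE_MARKER: 224.0}

_AUTOSOMES = [f"chr{i}" for i in range(1, 20)]  # mouse: chr1..chr19


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate an eight-cell-embryo-style design: 6 males vs 6
    females, a genome of 2000 autosomal / 100 X / 10 Y genes, NB dispersion
    0.05, full 2x female X dosage, and 3% of autosomal genes planted
    dimorphic at |log2FC| = 2.
    """

    n_autosomal: int = 2000
    n_x: int = 100
    n_y: int = 10
    n_male: int = 6
    n_female: int = 6
    baseline_log_mean_mu: float = 5.0   # log2 scale; ~32 counts
    baseline_log_mean_sd: float = 2.0
    dispersion: float | Sequence[float] = 0.05
    x_dosage_log2: float = 1.0          # female-over-male log2 shift on X genes
    dimorphic_fraction: float = 0.03
    effect_size_log2: float = 2.0
    min_planted_log2_mean: float = 4.0  # plant effects on expressed genes only
    library_size_mu: float = 1.0
    library_size_cv: float = 0.2
    xist_log2fc: float = XIST_LOG2FC
    eif2s3y_log2fc: float = EIF2S3Y_LOG2FC
    batch_effect_log2: float = 0.0      # optional litter/batch hook, off by default
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_autosomal", "n_x", "n_y", "n_male", "n_female"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_male + self.n_female < 2:
            raise InvalidConfigError("need at least 2 samples in total")
        disp = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if (disp <= 0).any():
            raise InvalidConfigError("dispersion must be > 0")
        if not 0 <= self.dimorphic_fraction <= 1:
            raise InvalidConfigError("dimorphic_fraction must be in [0, 1]")
        if self.library_size_mu <= 0 or self.library_size_cv < 0:
            raise InvalidConfigError("library size parameters must be positive")

    @property
    def n_genes(self) -> int:
        return self.n_autosomal + self.n_x + self.n_y

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Per-gene planted truth: dimorphism flag, true log2FC (male/female),
    chromosome class. Y genes silent in females carry an infinite log2FC."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def dimorphic_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_dimorphic"]])

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("gene").to_csv(path, sep="\t")


def simulate_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Gene models on chr1..chr19 / chrX / chrY with non-overlapping
    intervals. Xist and Eif2s3y are always present when n_x >= 1 and
    n_y >= 1 (as the first X and Y genes)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[tuple] = []
    per_chrom_cursor: dict[str, int] = {}

    def place(gene_id: str, chrom: str) -> None:
        start = per_chrom_cursor.get(chrom, 10_000)
        length = int(rng.integers(2_000, 50_000))
        strand = "+" if rng.random() < 0.5 else "-"
        records.append((gene_id, chrom, start, start + length, strand))
        per_chrom_cursor[chrom] = start + length + int(rng.integers(5_000, 20_000))

    for i in range(config.n_autosomal):
        place(f"GeneA{i:05d}", _AUTOSOMES[i % len(_AUTOSOMES)])
    for i in range(config.n_x):
        place(FEMALE_MARKER if i == 0 else f"GeneX{i:05d}", "chrX")
    for i in range(config.n_y):
        place(MALE_MARKER if i == 0 else f"GeneY{i:05d}", "chrY")

    df = pd.DataFrame(records, columns=["gene", "chrom", "start", "end", "strand"])
    return GeneAnnotation(df.set_index("gene"))


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draw with mean mu, variance mu + alpha*mu^2 (gamma-Poisson)."""
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        shape = 1.0 / alpha[pos]
        lam = rng.gamma(shape, mu[pos] * alpha[pos])
        out[pos] = rng.poisson(lam)
    return out


def simulate_counts(
    annotation: GeneAnnotation, config: SimulationConfig
) -> tuple[CountMatrix, GroundTruth]:
    """NB count matrix with planted sex effects, plus the ground truth.

    Female X genes are shifted up by ``x_dosage_log2``; Y genes are exactly
    zero in females; the Xist/Eif2s3y markers get their reference effect
    sizes; ``dimorphic_fraction`` of autosomal genes get sign-balanced
    effects of magnitude ``effect_size_log2``. Effects are applied
    symmetrically (+t/2 to males, -t/2 to females) so the male/female mean
    ratio is exactly 2**t.
    """
    config.validate()
    genes = annotation.gene_ids
    if len(genes) != config.n_genes:
        raise InvalidConfigError(
            f"annotation has {len(genes)} genes but config implies {config.n_genes}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_genes = len(genes)
    cls = annotation.table["cls"].to_numpy()

    base_log2 = rng.normal(config.baseline_log_mean_mu, config.baseline_log_mean_sd, n_genes)
    q = np.exp2(base_log2)
    alpha = np.broadcast_to(
        np.atleast_1d(np.asarray(config.dispersion, dtype=float)), (n_genes,)
    ).copy()

    true_lfc = np.zeros(n_genes)  # log2(male/female)
    is_x = cls == "X"
    is_y = cls == "Y"
    true_lfc[is_x] = -config.x_dosage_log2
    true_lfc[is_y] = np.inf  # female-silent

    # dimorphic signatures are defined within the detected-gene universe, so
    # effects are planted on adequately expressed autosomal genes
    auto_idx = np.flatnonzero(cls == "autosome")
    n_planted = int(round(config.dimorphic_fraction * auto_idx.size))
    eligible = auto_idx[base_log2[auto_idx] >= config.min_planted_log2_mean]
    if n_planted > eligible.size:
        eligible = auto_idx[np.argsort(base_log2[auto_idx])[-n_planted:]]
    planted = rng.choice(eligible, size=n_planted, replace=False)
    signs = np.where(np.arange(n_planted) % 2 == 0, 1.0, -1.0)
    true_lfc[planted] = signs * config.effect_size_log2

    marker_pos = {g: i for i, g in enumerate(genes) if g in (FEMALE_MARKER, MALE_MARKER)}
    if FEMALE_MARKER in marker_pos:
        i = marker_pos[FEMALE_MARKER]
        true_lfc[i] = config.xist_log2fc
        q[i] = _MARKER_BASE_MEAN[FEMALE_MARKER]
    if MALE_MARKER in marker_pos:
        i = marker_pos[MALE_MARKER]
        # realised as male-only expression (Y genes are female-silent)
        true_lfc[i] = config.eif2s3y_log2fc if config.eif2s3y_log2fc != 0 else np.inf
        q[i] = _MARKER_BASE_MEAN[MALE_MARKER]

    # Y effects are realised by female silence, not by a mean shift
    half = np.where(np.isfinite(true_lfc) & ~is_y, true_lfc / 2.0, 0.0)
    mu_male = q * np.exp2(half)
    mu_female = np.where(is_y, 0.0, q * np.exp2(-half))

    n_samples = config.n_male + config.n_female
    sigma2 = np.log(1.0 + config.library_size_cv**2)
    lib = rng.lognormal(
        np.log(config.library_size_mu) - sigma2 / 2.0, np.sqrt(sigma2), n_samples
    )
    is_male_sample = np.array([True] * config.n_male + [False] * config.n_female)

    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for s in range(n_samples):
        mu = (mu_male if is_male_sample[s] else mu_female) * lib[s]
        counts[:, s] = _nb_sample(rng, mu, alpha)

    sample_ids = [f"M{i+1:02d}" for i in range(config.n_male)] + [
        f"F{i+1:02d}" for i in range(config.n_female)
    ]
    meta = pd.DataFrame(
        {
            "sex": np.where(is_male_sample, "male", "female"),
            "stage": "synthetic",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids), meta)
    truth = GroundTruth(
        pd.DataFrame(
            {
                "is_dimorphic": true_lfc != 0,
                "true_log2fc_male_over_female": true_lfc,
                "cls": cls,
            },
            index=genes,
        )
    )
    return cm, truth


def simulate_tss_coverage(
    annotation: GeneAnnotation,
    dosage_ratio_female_over_male: float = 2.0,
    enriched_set: Iterable[str] = (),
    set_effect: float = 1.0,
    mean_reads: float = 500.0,
    gene_weight_log2_sd: float = 0.7,
    seed: int = 0,
) -> tuple[TSSWindowCounts, TSSWindowCounts]:
    """Per-sex TSS window read counts for the dosage model.

    Male expectation per gene is ``mean_reads`` times a log-normal per-gene
    weight; the female expectation multiplies X genes by
    ``dosage_ratio_female_over_male`` and genes in ``enriched_set``
    additionally by ``set_effect``. Counts are Poisson. Y genes are absent
    from the female track.
    """
    if dosage_ratio_female_over_male <= 0:
        raise InvalidConfigError("dosage ratio must be > 0")
    if set_effect <= 0:
        raise InvalidConfigError("set_effect must be > 0")
    if mean_reads < 0:
        raise InvalidConfigError("mean_reads must be >= 0")
    x_genes = set(annotation.x_genes)
    enriched = list(enriched_set)
    unknown = [g for g in enriched if g not in x_genes]
    if unknown:
        raise UnknownGeneError(
            f"enriched_set gene {unknown[0]!r} is not an X gene of the annotation"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    genes = annotation.gene_ids
    cls = annotation.table["cls"].to_numpy()
    weight = np.exp2(rng.normal(0.0, gene_weight_log2_sd, len(genes)))

    mu_male = mean_reads * weight
    female_scale = np.where(cls == "X", dosage_ratio_female_over_male, 1.0)
    in_set = np.asarray(genes.isin(enriched))
    female_scale = female_scale * np.where(in_set, set_effect, 1.0)
    mu_female = np.where(cls == "Y", 0.0, mu_male * female_scale)

    male_counts = rng.poisson(mu_male).astype(float)
    female_counts = rng.poisson(mu_female).astype(float)
    non_y = cls != "Y"
    male = TSSWindowCounts(
        values=pd.Series(male_counts, index=genes, name="tss_reads"),
        sex="male",
        kind="total",
        total_excl_y=float(male_counts[non_y].sum()),
    )
    female = TSSWindowCounts(
        values=pd.Series(female_counts, index=genes, name="tss_reads"),
        sex="female",
        kind="total",
        total_excl_y=float(female_counts[non_y].sum()),
    )
    return male, female


def write_dataset(
    directory: str | Path,
    config: SimulationConfig,
    annotation: GeneAnnotation,
    counts: CountMatrix,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write annotation (BED6), counts/metadata/truth (TSV) and config (YAML)."""
    from . import io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": directory / "annotation.bed",
        "counts": directory / "counts.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "ground_truth.tsv",
        "config": directory / "sim_config.yaml",
    }
    io.write_annotation_bed(annotation, paths["annotation"])
    io.write_counts(counts, paths["counts"], paths["metadata"])
    truth.to_tsv(paths["truth"])
    config.to_yaml(paths["config"])
    return paths
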