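"""End-to-end pipeline driven by a YAML config.

Stages mirror the analysis order of a sex-dimorphism study: sex calling
(where metadata sexes are unknown) -> dimorphism signature per dataset ->
projection of a chosen signature onto the other datasets with consistency
statistics -> optional ChIP-seq dosage-model fold enrichment -> optional
signature overlap. Every stochastic step takes an explicit seed, outputs
are plain TSVs, and a plain-text run log records versions, seeds and
thresholds.
"""
from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__, io
from .dimorphism import DimorphismModel
from .dosage import DosageModel
from .enrichment import overlap_fold_enrichment
from .exceptions import DimorphSeqError, InvalidConfigError
from .projection import directional_consistency, project_logfc
from .sexcall import apply_sex_calls, call_sex


@dataclass
class DatasetConfig:
    name: str
    counts: Path
    metadata: Path
    call_sex: bool = False
    stage: str = ""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``run.yaml`` in the README)."""

    output_dir: Path
    annotation: Path
    datasets: list[DatasetConfig]
    signature_dataset: str
    padj_threshold: float = 0.1
    lfc_threshold: float = 0.5
    halfwidth: int = 1500
    n_permutations: int = 1000
    seed: int = 0
    project_onto: list[str] = field(default_factory=list)
    consistency_pair: tuple[str, str] | None = None
    overlap_pair: tuple[str, str] | None = None
    chipseq: dict[str, Any] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        try:
            datasets = [
                DatasetConfig(
                    name=d["name"],
                    counts=resolve(d["counts"]),
                    metadata=resolve(d["metadata"]),
                    call_sex=bool(d.get("call_sex", False)),
                    stage=str(d.get("stage", "")),
                )
                for d in raw["datasets"]
            ]
            thresholds = raw.get("thresholds", {})
            chip = raw.get("chipseq")
            if chip is not None:
                chip = dict(chip)
                chip["male"] = [resolve(p) for p in chip["male"]]
                chip["female"] = [resolve(p) for p in chip["female"]]
                if isinstance(chip.get("gene_set"), str) and chip["gene_set"] != "signature_x":
                    chip["gene_set"] = resolve(chip["gene_set"])
            cfg = cls(
                output_dir=resolve(raw["output_dir"]),
                annotation=resolve(raw["annotation"]),
                datasets=datasets,
                signature_dataset=raw["signature_dataset"],
                padj_threshold=float(thresholds.get("padj", 0.1)),
                lfc_threshold=float(thresholds.get("lfc", 0.5)),
                halfwidth=int(thresholds.get("halfwidth", 1500)),
                n_permutations=int(raw.get("n_permutations", 1000)),
                seed=int(raw.get("seed", 0)),
                project_onto=list(raw.get("project_onto", [])),
                consistency_pair=tuple(raw["consistency"].values()) if "consistency" in raw else None,
                overlap_pair=tuple(raw["overlap"].values()) if "overlap" in raw else None,
                chipseq=chip,
            )
        except KeyError as exc:
            raise InvalidConfigError(f"pipeline config missing key {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        names = [d.name for d in self.datasets]
        if len(set(names)) != len(names):
            raise InvalidConfigError("dataset names must be unique")
        if self.signature_dataset not in names:
            raise InvalidConfigError(
                f"signature_dataset {self.signature_dataset!r} is not a configured dataset"
            )
        paths = [self.annotation] + [p for d in self.datasets for p in (d.counts, d.metadata)]
        if self.chipseq:
            paths += list(self.chipseq["male"]) + list(self.chipseq["female"])
            if isinstance(self.chipseq.get("gene_set"), Path):
                paths.append(self.chipseq["gene_set"])
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise InvalidConfigError(f"configured files do not exist: {missing}")
        for other in self.project_onto:
            if other not in names:
                raise InvalidConfigError(f"project_onto names unknown dataset {other!r}")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except DimorphSeqError as exc:
                raise DimorphSeqError(f"stage {name!r}: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig | str | Path) -> dict[str, Any]:
    """Run the configured analysis; returns the summary dict that is also
    written to ``summary.yaml`` in the output directory."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger = logging.getLogger("dimorphseq.pipeline")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out, logger)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path, logger: logging.Logger) -> dict[str, Any]:
    logger.info(
        "dimorphseq %s | seed=%d padj<%g |log2FC|>%g halfwidth=%d n_perm=%d",
        __version__,
        config.seed,
        config.padj_threshold,
        config.lfc_threshold,
        config.halfwidth,
        config.n_permutations,
    )
    annotation = _stage("read_annotation")(io.read_annotation)(config.annotation)
    summary: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "padj": config.padj_threshold,
            "lfc": config.lfc_threshold,
            "halfwidth": config.halfwidth,
        },
        "datasets": {},
    }

    results = {}
    signatures = {}
    for ds in config.datasets:
        logger.info("dataset %s: reading %s", ds.name, ds.counts)
        cm = _stage(f"read_counts[{ds.name}]")(io.read_counts)(ds.counts, ds.metadata)
        if ds.call_sex or (cm.sex == "unknown").any():
            calls = _stage(f"call_sex[{ds.name}]")(call_sex)(cm)
            calls.rename_axis("sample_id").to_csv(out / f"{ds.name}.sex_calls.tsv", sep="\t")
            cm = apply_sex_calls(cm, calls, force=ds.call_sex)
            logger.info(
                "dataset %s: called %d male / %d female",
                ds.name,
                (calls["sex"] == "male").sum(),
                (calls["sex"] == "female").sum(),
            )
        res = _stage(f"dimorphism[{ds.name}]")(
            lambda c: DimorphismModel(c, annotation=annotation).fit()
        )(cm)
        res.to_table1_style().to_csv(out / f"{ds.name}.dimorphism.tsv", sep="\t")
        sig = res.signature(config.padj_threshold, config.lfc_threshold)
        sig.table.rename_axis("gene").to_csv(out / f"{ds.name}.signature.tsv", sep="\t")
        by_class = sig.counts_by_class().to_dict() if len(sig) else {}
        results[ds.name] = (cm, res)
        signatures[ds.name] = sig
        summary["datasets"][ds.name] = {
            "n_samples": cm.n_samples,
            "n_male": len(cm.samples_of_sex("male")),
            "n_female": len(cm.samples_of_sex("female")),
            "n_tested": res.n_tested,
            "signature_size": len(sig),
            "signature_by_class": {str(k): int(v) for k, v in by_class.items()},
        }
        logger.info("dataset %s: signature of %d genes %s", ds.name, len(sig), by_class)

    sig_name = config.signature_dataset
    sig = signatures[sig_name]
    targets = config.project_onto or [d.name for d in config.datasets if d.name != sig_name]
    projections = {}
    summary["projection"] = {}
    for target in targets:
        cm, _ = results[target]
        proj = _stage(f"project[{target}]")(project_logfc)(sig, cm, dataset=target)
        proj.table.rename_axis("gene").to_csv(
            out / f"projection.{sig_name}_onto_{target}.tsv", sep="\t"
        )
        projections[target] = proj
        entry: dict[str, Any] = {
            "n_projected": len(proj.table),
            "n_missing": len(proj.missing),
            "n_conserved": int(proj.table["conserved"].sum()),
        }
        if "cls" in proj.table.columns:
            entry["class_median_log2fc"] = {
                str(k): float(v) for k, v in proj.class_summary()["median"].items()
            }
        summary["projection"][target] = entry

    if config.consistency_pair:
        a_name, b_name = config.consistency_pair
        lfc_a = results[a_name][1].table.query("tested")["log2fc"]
        lfc_b = results[b_name][1].table.query("tested")["log2fc"]
        shared_sig = [g for g in sig.gene_ids if g in lfc_a.index and g in lfc_b.index]
        cons = _stage("consistency")(directional_consistency)(
            lfc_a.loc[shared_sig], lfc_b.loc[shared_sig]
        )
        summary["consistency"] = {
            "a": a_name,
            "b": b_name,
            "n_same_sign": cons.n_same_sign,
            "n_opposite_sign": cons.n_opposite_sign,
            "fraction_consistent": cons.fraction_consistent,
            "chi_square": cons.chi_square,
            "pvalue": cons.pvalue,
        }
        logger.info("consistency %s vs %s: %s", a_name, b_name, summary["consistency"])

    if config.overlap_pair:
        a_name, b_name = config.overlap_pair
        background = sorted(
            set(results[a_name][1].table.query("tested").index)
            & set(results[b_name][1].table.query("tested").index)
        )
        ov = _stage("overlap")(overlap_fold_enrichment)(
            [g for g in signatures[a_name].gene_ids if g in background],
            [g for g in signatures[b_name].gene_ids if g in background],
            background,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        summary["overlap"] = {
            "a": a_name,
            "b": b_name,
            "n_overlap": ov.n_overlap,
            "fold_enrichment": ov.fold_enrichment,
            "permutation_pvalue": ov.pvalue,
            "hypergeometric_pvalue": ov.hypergeometric_pvalue,
        }
        logger.info("overlap %s vs %s: %s", a_name, b_name, ov)

    if config.chipseq:
        chip = config.chipseq
        male = [
            _stage("tss_coverage")(io.average_over_tss)(
                p, annotation, halfwidth=config.halfwidth, sex="male"
            )
            for p in chip["male"]
        ]
        female = [
            _stage("tss_coverage")(io.average_over_tss)(
                p, annotation, halfwidth=config.halfwidth, sex="female"
            )
            for p in chip["female"]
        ]
        fit = _stage("dosage_model")(lambda: DosageModel(male, female, annotation).fit())()
        fit.table.rename_axis("gene").to_csv(out / "dosage_model.tsv", sep="\t")
        gene_set_cfg = chip.get("gene_set", "signature_x")
        if gene_set_cfg == "signature_x":
            gene_set = [g for g in sig.genes_of_class("X") if g in fit.table.index]
        else:
            gene_set = [g for g in io.read_gene_list(gene_set_cfg) if g in fit.table.index]
        fe = _stage("dosage_fe")(fit.permutation_test)(
            gene_set,
            n_permutations=config.n_permutations,
            seed=config.seed,
            set_id=f"{sig_name}_x_genes",
        )
        summary["dosage"] = {
            "fe_female": fe.fe_female,
            "pvalue": fe.pvalue,
            "set_size": fe.set_size,
            "background_size": fe.background_size,
            "n_permutations": fe.n_permutations,
        }
        logger.info("dosage FE: %s", fe)

    summary["finished"] = datetime.datetime.now().isoformat(timespec="seconds")
    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(
            {k: v for k, v in summary.items() if k != "finished"}, fh, sort_keys=False
        )
    logger.info("pipeline finished")
    return summary
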