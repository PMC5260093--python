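"""End-to-end orchestration: filter → select → classify → infer → compare.

`run_all` drives the whole workflow from a :class:`PipelineConfig` and a run
directory, writing every intermediate artifact (filter report, feature sets,
classification table, per-class consensus networks, degree table,
differential edges) plus a JSON manifest of parameters and derived seeds.
Rerunning with the same config and seed reproduces the outputs.

A single global seed fans out to per-stage seeds via a stable hash of the
stage name, so an individual stage rerun matches the full-run result.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import classify, consensus, datagen, diffnet, features, io, netinfer

__all__ = ["PipelineConfig", "run_all", "derive_seed"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Paths, thresholds and scale settings for a full run.

    When ``expression_path`` is None a synthetic dataset is generated with
    ``synthetic`` (a :class:`~scgrn.datagen.SyntheticConfig`).
    """

    expression_path: str | None = None
    labels_path: str | None = None
    genesets_path: str | None = None
    synthetic: datagen.SyntheticConfig | None = None
    filter_rule: str = "main_text"
    filter_threshold: float = 1.0
    filter_min_cells: int = 6
    log_base: int | str = 2
    pseudocount: float = 1.0
    gsva_alpha: float = 0.005
    ttest_alpha: float = 0.05
    srap_fdr: float = 0.05
    srap_min_abs_lfc: float = 0.58
    svm_rfe_size_grid: list[int] | None = None
    rf_mda_trees: int = 500
    classifier: classify.ClassifierSpec | None = None
    network_genes_from: str = "svm_rfe"
    confidence_threshold: float = 0.75
    differential_threshold: float = 0.75
    profile: str = "desk"
    seed: int = 0

    def to_manifest(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("synthetic", "classifier")}
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.__dict__
        if self.classifier is not None:
            d["classifier"] = {k: v for k, v in self.classifier.__dict__.items()}
        return d


def _load_or_generate(cfg: PipelineConfig, outdir: Path):
    if cfg.expression_path is not None:
        if cfg.labels_path is None:
            raise RuntimeError("stage preprocess failed: labels file required")
        m = io.read_expression(cfg.expression_path, labels_path=cfg.labels_path)
        genesets = features.read_gmt(cfg.genesets_path) if cfg.genesets_path else None
        truth = None
    else:
        syn = cfg.synthetic or datagen.SyntheticConfig(seed=derive_seed(cfg.seed, "simulate"))
        m, truth = datagen.generate_dataset(syn)
        genesets = datagen.generate_genesets(
            truth, n_sets=10, set_size=20,
            seed=derive_seed(cfg.seed, "genesets"), universe=m.gene_ids)
        m.write_tsv(outdir / "expression.tsv")
        m.write_labels(outdir / "labels.tsv")
        datagen.write_gmt(genesets, outdir / "genesets.gmt")
        truth.write(outdir / "ground_truth.json")
    return m, genesets, truth


def run_all(config: PipelineConfig, outdir) -> Path:
    """Execute the full workflow; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_manifest(), "stages": {}, "seeds": {}}
    t0 = time.time()
    stage = "preprocess"
    try:
        m_raw, genesets, _truth = _load_or_generate(config, outdir)
        logged = io.log_transform(m_raw, base=config.log_base,
                                  pseudocount=config.pseudocount)
        filtered, report = io.filter_genes(
            logged, rule=config.filter_rule, threshold=config.filter_threshold,
            min_cells=config.filter_min_cells)
        report.write(outdir / "filter_report.tsv", outdir / "filter_report.json")
        manifest["stages"]["preprocess"] = {"n_retained": report.n_retained}

        stage = "select"
        sel_seed = derive_seed(config.seed, "select")
        manifest["seeds"]["select"] = sel_seed
        fsets: dict[str, features.FeatureSet] = {}
        fsets["ttest"] = features.select_ttest(filtered, alpha=config.ttest_alpha)
        fsets["srap_de"] = features.select_srap_de(
            filtered, fdr=config.srap_fdr, min_abs_lfc=config.srap_min_abs_lfc)
        if genesets is not None:
            fsets["gsva"] = features.select_gsva(filtered, genesets,
                                                 alpha=config.gsva_alpha)
        fsets["svm_rfe"] = features.select_svm_rfe(
            filtered, size_grid=config.svm_rfe_size_grid, seed=sel_seed)
        fsets["rf_mda"] = features.select_rf_mda(
            filtered, n_trees=config.rf_mda_trees, seed=sel_seed)
        for name, fs in fsets.items():
            fs.write_tsv(outdir / f"features_{name}.tsv")
        manifest["stages"]["select"] = {k: len(v) for k, v in fsets.items()}

        stage = "classify"
        spec = config.classifier or classify.ClassifierSpec(
            seed=derive_seed(config.seed, "classify"))
        eval_sets: dict[str, features.FeatureSet | None] = {"all_genes": None}
        eval_sets.update({k: v for k, v in fsets.items() if len(v) > 0})
        table2 = classify.run_table2(filtered, eval_sets, spec)
        table2.to_csv(outdir / "classification_table.tsv", sep="\t")
        manifest["stages"]["classify"] = {"rows": len(table2)}

        stage = "infer"
        net_fs = fsets.get(config.network_genes_from)
        if net_fs is None or len(net_fs) < 3:
            net_fs = fsets["ttest"]
        net_genes = [g for g in net_fs.genes
                     if (filtered.values.loc[g,
                         filtered.class_cells(io.CLASS_A)] > 0).any()]
        net_m = filtered.subset_genes(net_genes)
        inf_seed = derive_seed(config.seed, "infer")
        manifest["seeds"]["infer"] = inf_seed
        registry = netinfer.default_registry(profile=config.profile, seed=inf_seed)
        nets = {}
        for label in (io.CLASS_A, io.CLASS_B):
            scores = netinfer.run_battery(net_m, registry, class_label=label)
            nets[label] = consensus.consensus_from_scores(scores, class_label=label)
            nets[label].write_tsv(outdir / f"consensus_{label}.tsv")
        manifest["stages"]["infer"] = {"n_network_genes": len(net_genes),
                                       "n_algorithms": len(registry)}

        stage = "diffnet"
        result = diffnet.run_diffnet(
            nets[io.CLASS_A], nets[io.CLASS_B],
            confidence_threshold=config.confidence_threshold,
            differential_threshold=config.differential_threshold)
        result.degree_table.to_csv(outdir / "degree_table.tsv", sep="\t",
                                   index_label="gene")
        result.differential.to_csv(outdir / "differential_edges.tsv", sep="\t",
                                   index=False)
        result.subnetwork_a.to_csv(outdir / "subnetwork_class_a.tsv", sep="\t",
                                   index=False)
        result.subnetwork_b.to_csv(outdir / "subnetwork_class_b.tsv", sep="\t",
                                   index=False)
        manifest["stages"]["diffnet"] = {
            "n_differential_edges": len(result.differential)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                         default=str))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))
    return outdir
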