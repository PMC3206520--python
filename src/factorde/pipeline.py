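"""End-to-end pipeline: simulate/load -> filter -> model -> classify ->
screen -> cluster -> enrich, with every intermediate written as TSV and a
run report echoing all parameters.

The report mirrors the headline summaries of a two-tissue time-course
experiment: probes surviving the filter, the four-category classification
(three-way, treatment x tissue, treatment x time, treatment-only) at probe
and gene level, per-tissue counts of large early fold changes, cluster
sizes, and the top enrichment hits. Every number in the report is
recomputable from the emitted TSVs; the whole run is deterministic given
the seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrich, model, preprocess, qtclust, simulate
from .design import TIMES_H, TISSUES, generate_design, read_design, write_design

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults follow the study settings
    (FDR alpha 0.05, 2-fold screen within 8 h, QT at 0.9 / 14)."""

    # input: either synthetic simulation or file paths
    synthetic: bool = True
    replicates: int = 3
    batches: int = 2
    sim: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    n_gene_sets: int = 20
    gene_set_size: int = 40
    enrichment_fraction: float = 0.8
    expression_tsv: str | None = None
    design_tsv: str | None = None
    annotation_tsv: str | None = None
    gmt: str | None = None

    # analysis parameters
    min_sd: float = 0.1
    min_mean: float = 0.0
    alpha: float = 0.05
    fold_threshold: float = 2.0
    window_h: int = 8
    covariate_policy: str = "always_include"
    t_variant: str = "pooled"
    min_correlation: float = 0.9
    min_cluster_size: int = 14
    cluster_classes: tuple = ("threeway", "treatment_x_tissue")
    enrichment_mode: str = "ora"  # or "preranked"
    weight_exponent: float = 1.0
    n_perm: int = 1000
    rank_tissue: str = "pancreas"
    rank_time_h: int = 8

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = simulate.SimulationConfig(**sim_raw)
        return cfg

    def validate(self) -> None:
        if not self.synthetic:
            for name in ("expression_tsv", "design_tsv", "annotation_tsv"):
                path = getattr(self, name)
                if path is None:
                    raise PipelineError(f"config: {name} required when synthetic=false")
                if not Path(path).exists():
                    raise PipelineError(f"config: {name} does not exist: {path}")
            if self.gmt is not None and not Path(self.gmt).exists():
                raise PipelineError(f"config: gmt does not exist: {self.gmt}")
        self.sim.validate()

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["cluster_classes"] = list(self.cluster_classes)
        return d


def summarize_counts(
    classification: pd.DataFrame,
    contrasts: pd.DataFrame,
    profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """Per-class probe/gene counts and per-tissue per-time >=fold counts.

    The fold-count table counts, among probes classified into any
    treatment-involving class, those whose |log2 fold change| meets the
    threshold in each (tissue, time) group — the per-tissue response-size
    table. Gene-level class counts collapse probes by best class p.
    """
    class_order = [
        "threeway",
        "treatment_x_tissue",
        "treatment_x_time",
        "treatment_only",
        "not_significant",
    ]
    probe_counts = {
        c: int((classification["assigned_class"] == c).sum()) for c in class_order
    }

    gene_table = preprocess.collapse_to_genes(
        classification, annotation, rule="best_p", p_col="class_p"
    )
    gene_counts = {
        c: int((gene_table["assigned_class"] == c).sum()) for c in class_order
    }
    significant = classification.loc[
        classification["assigned_class"] != "not_significant", "probe_id"
    ]
    sig_genes = gene_table[gene_table["assigned_class"] != "not_significant"]

    lfc_cut = float(np.log2(config.fold_threshold))
    sig_contrasts = contrasts[contrasts["probe_id"].isin(set(significant))]
    fold_counts = {}
    for tissue in TISSUES:
        fold_counts[tissue] = {}
        for t in TIMES_H:
            sub = sig_contrasts[
                (sig_contrasts["tissue"] == tissue) & (sig_contrasts["time_h"] == t)
            ]
            fold_counts[tissue][int(t)] = int((sub["log2_fc"].abs() >= lfc_cut).sum())

    return {
        "probe_class_counts": probe_counts,
        "gene_class_counts": gene_counts,
        "n_significant_probes": int(len(significant)),
        "n_significant_genes": int(len(sig_genes)),
        "fold_responder_counts": fold_counts,
    }


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage {name}: {e}") from e

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages, write artifacts under ``outdir``, return the report."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("factorde")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    logger.info("pipeline parameters: %s", config.echo())

    # ---- inputs -----------------------------------------------------------
    truth = None
    gene_sets = None
    if config.synthetic:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        design = generate_design(config.replicates, config.batches, seed=config.seed)
        matrix, truth = simulate.simulate_expression(design, sim_cfg)
        annotation = simulate.make_probe_annotation(truth, seed=config.seed + 1)
        if config.n_gene_sets > 0:
            gene_sets = simulate.plant_gene_sets(
                truth,
                config.n_gene_sets,
                config.gene_set_size,
                config.enrichment_fraction,
                seed=config.seed + 2,
            )
        write_design(design, outdir / "design.tsv")
        matrix.to_csv(outdir / "expression.tsv", sep="\t")
        simulate.write_truth(truth, outdir / "truth.tsv")
        annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        if gene_sets is not None:
            gene_sets.to_gmt(outdir / "gene_sets.gmt")
    else:
        design = read_design(config.design_tsv)
        matrix = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
        matrix.index.name = "probe_id"
        annotation = pd.read_csv(config.annotation_tsv, sep="\t")
        if config.gmt:
            gene_sets = enrich.GeneSetCollection.from_gmt(config.gmt)

    # ---- filter -----------------------------------------------------------
    filtered = _stage("filter")(preprocess.filter_probes)(
        matrix, annotation, min_sd=config.min_sd, min_mean=config.min_mean
    )
    filtered.to_csv(outdir / "filtered_expression.tsv", sep="\t")
    logger.info("filter: %d of %d probes survive", len(filtered), len(matrix))

    # ---- fold-change profiles --------------------------------------------
    profiles = _stage("fold_change")(preprocess.fold_change_profiles)(filtered, design)
    preprocess.profiles_long(profiles).to_csv(
        outdir / "fold_change.tsv", sep="\t", index=False
    )

    # ---- factorial model --------------------------------------------------
    spec = model.ModelSpec(covariate_policy=config.covariate_policy)
    term_stats = _stage("anova")(model.term_anova)(filtered, design, spec)
    term_stats = _stage("fdr")(model.adjust_fdr)(term_stats)
    term_stats.to_csv(outdir / "term_stats.tsv", sep="\t", index=False)

    classification = _stage("classify")(model.classify_probes)(
        term_stats, alpha=config.alpha
    )
    classification.to_csv(outdir / "classification.tsv", sep="\t", index=False)

    # ---- contrasts and early responders ----------------------------------
    contrasts = _stage("contrasts")(model.contrast_tests)(
        filtered, design, t_variant=config.t_variant
    )
    contrasts.to_csv(outdir / "contrasts.tsv", sep="\t", index=False)
    early = _stage("early_responders")(model.flag_early_responders)(
        profiles, contrasts, config.fold_threshold, config.window_h
    )
    early.to_csv(outdir / "early_responders.tsv", sep="\t", index=False)

    # ---- QT clustering ----------------------------------------------------
    cluster_probes = classification.loc[
        classification["assigned_class"].isin(config.cluster_classes), "probe_id"
    ]
    cluster_input = profiles.loc[profiles.index.isin(set(cluster_probes))]
    variances = cluster_input.to_numpy().std(axis=1)
    cluster_input = cluster_input.loc[variances > 0]
    params = qtclust.ClusterParams(
        min_correlation=config.min_correlation,
        min_cluster_size=config.min_cluster_size,
    )
    clusters = _stage("qt_cluster")(qtclust.qt_cluster)(cluster_input, params)
    clusters.membership().to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    clusters.summary().to_csv(outdir / "cluster_summary.tsv", sep="\t", index=False)
    ordered_ids = [m for c in clusters.clusters for m in c.members]
    cluster_input.loc[ordered_ids].to_csv(
        outdir / "cluster_ordered_matrix.tsv", sep="\t"
    )

    # ---- enrichment -------------------------------------------------------
    enrichment_summary: dict = {"mode": None, "n_sets": 0, "top_sets": []}
    if gene_sets is not None and len(gene_sets) > 0:
        universe = list(filtered.index)
        if config.enrichment_mode == "ora":
            selected = sorted(set(early["probe_id"]) & set(universe))
            table = _stage("enrichment")(enrich.ora_table)(
                selected, universe, gene_sets
            )
            sort_col = "p_adj"
        else:
            sub = contrasts[
                (contrasts["tissue"] == config.rank_tissue)
                & (contrasts["time_h"] == config.rank_time_h)
            ].set_index("probe_id")
            scores = -np.log10(np.maximum(sub["p"], 1e-300)) * np.sign(sub["log2_fc"])
            ranked = scores.sort_values(ascending=False)
            table = _stage("enrichment")(enrich.es_permutation_fdr)(
                ranked,
                gene_sets,
                n_perm=config.n_perm,
                seed=config.seed + 3,
                weight_exponent=config.weight_exponent,
            )
            sort_col = "q"
        table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        top = table.nsmallest(5, sort_col) if len(table) else table
        enrichment_summary = {
            "mode": config.enrichment_mode,
            "n_sets": int(len(table)),
            "top_sets": [
                {"set": r["set"], sort_col: float(r[sort_col])}
                for _, r in top.iterrows()
            ],
        }

    # ---- report -----------------------------------------------------------
    counts = summarize_counts(classification, contrasts, profiles, annotation, config)
    report = {
        "config": config.echo(),
        "seed": config.seed,
        "n_probes_input": int(len(matrix)),
        "n_probes_filtered": int(len(filtered)),
        **counts,
        "early_responders": {
            tissue: int((early["tissue"] == tissue).sum()) for tissue in TISSUES
        },
        "clusters": {
            "n_clusters": len(clusters.clusters),
            "sizes": [len(c.members) for c in clusters.clusters],
            "n_unclustered": len(clusters.unclustered),
        },
        "enrichment": enrichment_summary,
    }
    with open(outdir / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    logger.info("pipeline complete: report written to %s", outdir / "report.yaml")
    return report
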