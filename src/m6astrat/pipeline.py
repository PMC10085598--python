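"""End-to-end orchestration of the subtyping-and-scoring analysis.

Stage order mirrors the analysis flow: regulator consensus clustering ->
cluster survival -> per-cluster enrichment and immune/stromal scores ->
pairwise differential expression with Venn intersection -> univariate Cox
screen -> gene-cluster consensus -> PCA m6A score -> high/low
stratification -> survival -> TMB and score associations -> two-cohort
clinical comparison.  A single seed fans out to per-stage seeds through a
counter so individual stages rerun reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from m6astrat.assoc_stats import cohort_comparison
from m6astrat.consensus_cluster import consensus_cluster
from m6astrat.diffexpr import moderated_f_test, venn_intersect
from m6astrat.enrichment import estimate_scores, ssgsea
from m6astrat.io_core import (ClinicalTable, CopyNumberTable, ExpressionMatrix,
                              GeneSetCollection, MutationTable, RegulatorPanel,
                              DEFAULT_REGULATOR_PANEL)
from m6astrat.mutation_genomics import compute_tmb, gene_mutation_frequency
from m6astrat.scoring import m6a_score, score_associations
from m6astrat.survival import cox_screen, logrank_test

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


@dataclass
class PipelineConfig:
    """Knobs of the full analysis; both clustering passes default to a
    pinned k=3 with the model-selection diagnostics always emitted."""

    k_regulator: int = 3
    k_gene: int = 3
    k_range: tuple[int, int] = (2, 9)
    reps: int = 250
    p_item: float = 0.8
    deg_p_threshold: float = 0.01
    deg_contrasts: str = "pairwise"  # or "omnibus"
    cox_p_threshold: float = 0.01
    cut_method: str = "median"
    ssgsea_alpha: float = 0.25
    marker_genes: tuple[str, ...] = ("CD274",)
    panel: RegulatorPanel = field(default_factory=lambda: DEFAULT_REGULATOR_PANEL)
    seed: int = 0

    def stage_seed(self, stage_index: int) -> int:
        return (self.seed * 1000 + stage_index) % (2**31 - 1)


@dataclass
class PipelineResult:
    config: PipelineConfig
    regulator_consensus: object
    m6a_clusters: pd.Series
    cluster_logrank: object
    enrichment: pd.DataFrame | None
    estimate: pd.DataFrame | None
    deg_table: pd.DataFrame
    intersect_genes: list[str]
    cox_table: pd.DataFrame
    prognostic_genes: list[str]
    gene_clusters: pd.Series
    gene_cluster_logrank: object
    scores: object
    score_logrank: object
    tmb: pd.DataFrame
    associations: pd.DataFrame
    mutation_frequency: pd.Series
    alluvial: pd.DataFrame
    table1: pd.DataFrame | None
    manifest: dict


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()[:16]


def run_pipeline(expr: ExpressionMatrix, clinical: ClinicalTable,
                 mutations: MutationTable | None = None,
                 copynumber: CopyNumberTable | None = None,
                 immune_sets: GeneSetCollection | None = None,
                 cohort_b: ClinicalTable | None = None,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on one cohort.

    Any stage failure raises :class:`StageError` naming the stage; results
    computed before the failure are attached to the exception.
    """
    cfg = config or PipelineConfig()
    partial: dict = {}
    stage = "init"
    try:
        clin = clinical.aligned(expr.sample_ids)
        known = clin["os_event"].isin([0, 1]) & clin["os_time"].notna()
        times = clin.loc[known, "os_time"].to_numpy(dtype=float)
        events = clin.loc[known, "os_event"].to_numpy().astype(int)
        surv_samples = np.array(expr.sample_ids)[known.to_numpy()]

        stage = "regulator_consensus"
        reg_expr = expr.subset_genes(cfg.panel.genes)
        cons = consensus_cluster(reg_expr, range(cfg.k_range[0], cfg.k_range[1] + 1),
                                 reps=cfg.reps, p_item=cfg.p_item,
                                 seed=cfg.stage_seed(1))
        m6a_clusters = cons.labels_series(cfg.k_regulator).map(
            lambda c: "ABCDEFGHIJ"[c])
        partial["regulator_consensus"] = cons

        stage = "cluster_survival"
        grp = m6a_clusters.loc[surv_samples].to_numpy()
        cluster_lr = logrank_test(times, events, grp)

        stage = "enrichment"
        enr = est = None
        if immune_sets is not None:
            enr = ssgsea(expr, immune_sets, alpha=cfg.ssgsea_alpha,
                         min_max_normalize=True).scores
            names = immune_sets.names()
            if len(names) >= 2:
                est = estimate_scores(expr, immune_sets[names[0]],
                                      immune_sets[names[1]],
                                      alpha=cfg.ssgsea_alpha).table

        stage = "differential_expression"
        deg = moderated_f_test(expr, m6a_clusters, p_threshold=cfg.deg_p_threshold)
        if cfg.deg_contrasts == "pairwise":
            per_contrast = deg.significant_per_contrast()
            intersect = venn_intersect(list(per_contrast.values()))
        else:
            intersect = deg.significant
        # the regulator panel itself is not part of the derived signature
        intersect = [g for g in intersect if g not in set(cfg.panel.genes)]

        stage = "cox_screen"
        if not intersect:
            raise ValueError("no intersected differential genes to screen")
        cox_tab = cox_screen(expr.values.loc[intersect, surv_samples], times, events,
                             p_threshold=cfg.cox_p_threshold)
        prognostic = list(cox_tab.index[cox_tab["significant"]])
        if len(prognostic) < 3:
            raise ValueError("fewer than 3 prognostic genes survive the screen")

        stage = "gene_consensus"
        gene_cons = consensus_cluster(expr.subset_genes(prognostic),
                                      range(cfg.k_range[0], cfg.k_range[1] + 1),
                                      reps=cfg.reps, p_item=cfg.p_item,
                                      seed=cfg.stage_seed(2))
        gene_clusters = gene_cons.labels_series(cfg.k_gene).map(
            lambda c: "ABCDEFGHIJ"[c])
        gene_lr = logrank_test(times, events,
                               gene_clusters.loc[surv_samples].to_numpy())

        stage = "m6a_score"
        scores = m6a_score(expr, prognostic, times=times, events=events,
                           cut_method=cfg.cut_method)
        sgrp = scores.table.loc[surv_samples, "group"].to_numpy()
        score_lr = logrank_test(times, events, sgrp)

        stage = "tmb_associations"
        tmb = assoc = mut_freq = None
        if mutations is not None:
            tmb = compute_tmb(mutations, expr.sample_ids)
            markers = [g for g in cfg.marker_genes if g in set(expr.gene_ids)]
            assoc = score_associations(
                scores, tmb=tmb["tmb"],
                marker_expr=expr.values.loc[markers] if markers else None,
                immune_scores=enr)
            mut_freq = gene_mutation_frequency(mutations, len(expr.sample_ids),
                                               panel=cfg.panel.genes)

        stage = "alluvial"
        alluvial = pd.DataFrame({
            "sample_id": expr.sample_ids,
            "m6a_cluster": m6a_clusters.loc[expr.sample_ids].to_numpy(),
            "gene_cluster": gene_clusters.loc[expr.sample_ids].to_numpy(),
            "score_group": scores.table.loc[expr.sample_ids, "group"].to_numpy(),
            "os_status": clin["os_event"].map({0: "alive", 1: "dead"}).fillna("unknown").to_numpy(),
        })

        stage = "cohort_comparison"
        table1 = cohort_comparison(clinical, cohort_b) if cohort_b is not None else None

        stage = "manifest"
        manifest = {
            "seed": cfg.seed,
            "parameters": {k: v for k, v in asdict(cfg).items() if k != "panel"},
            "n_samples": len(expr.sample_ids),
            "n_genes": len(expr.gene_ids),
            "n_intersect_genes": len(intersect),
            "n_prognostic_genes": len(prognostic),
            "hashes": {
                "expression": _hash_frame(expr.values),
                "clusters": _hash_frame(m6a_clusters.to_frame()),
                "scores": _hash_frame(scores.table),
                "alluvial": _hash_frame(alluvial),
            },
        }
        return PipelineResult(
            config=cfg, regulator_consensus=cons, m6a_clusters=m6a_clusters,
            cluster_logrank=cluster_lr, enrichment=enr, estimate=est,
            deg_table=deg.table, intersect_genes=intersect, cox_table=cox_tab,
            prognostic_genes=prognostic, gene_clusters=gene_clusters,
            gene_cluster_logrank=gene_lr, scores=scores, score_logrank=score_lr,
            tmb=tmb, associations=assoc, mutation_frequency=mut_freq,
            alluvial=alluvial, table1=table1, manifest=manifest,
        )
    except StageError:
        raise
    except Exception as exc:
        err = StageError(f"pipeline stage {stage!r} failed: {exc}")
        err.stage = stage
        err.partial = partial
        raise err from exc


def make_report(result: PipelineResult) -> str:
    """Deterministic Markdown summary of a completed run."""
    required = ("m6a_clusters", "scores", "cluster_logrank", "score_logrank")
    missing = [f for f in required if getattr(result, f, None) is None]
    if missing:
        raise ValueError(f"incomplete result bundle; missing stages: {missing}")
    cfg = result.config
    lines = ["# m6A subtyping and scoring report", ""]
    sizes = result.m6a_clusters.value_counts().sort_index()
    lines += [f"Pinned k (regulator clustering): {cfg.k_regulator}; "
              f"pinned k (gene clustering): {cfg.k_gene}", ""]
    lines += ["## m6A clusters",
              ", ".join(f"{c}: n={n}" for c, n in sizes.items()),
              f"Log-rank across clusters: chi2={result.cluster_logrank.statistic:.3f}, "
              f"p={result.cluster_logrank.p_value:.3g}", ""]
    if not result.prognostic_genes:
        lines += ["## Signature", "DEGENERATE: empty prognostic gene set", ""]
    else:
        lines += ["## Signature",
                  f"{len(result.intersect_genes)} intersected differential genes; "
                  f"{len(result.prognostic_genes)} prognostic after Cox screen "
                  f"(p < {cfg.cox_p_threshold})", ""]
    st = result.scores.table
    lines += ["## m6A score",
              f"cut method: {result.scores.cut_method}, threshold "
              f"{result.scores.threshold:.4f}",
              f"high/low sizes: {int((st['group'] == 'high').sum())}/"
              f"{int((st['group'] == 'low').sum())}",
              f"score mean {st['m6a_score'].mean():.4f}, sd {st['m6a_score'].std():.4f}",
              f"Log-rank high vs low: chi2={result.score_logrank.statistic:.3f}, "
              f"p={result.score_logrank.p_value:.3g}", ""]
    if result.associations is not None:
        tmb_row = result.associations[result.associations["feature"] == "tmb"]
        if not tmb_row.empty:
            lines += ["## Associations",
                      f"Spearman(score, TMB) rho={tmb_row['statistic'].iloc[0]:.3f}, "
                      f"p={tmb_row['p'].iloc[0]:.3g}", ""]
    if result.deg_table is not None:
        top = result.deg_table.nsmallest(10, "p_value").index.tolist()
        lines += ["## Top differential genes", ", ".join(top), ""]
    if result.table1 is not None:
        lines += ["## Cohort comparison", result.table1.to_string(index=False), ""]
    return "\n".join(lines)


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    """Write the run's tables, manifest and report under a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.m6a_clusters.rename("m6a_cluster").to_csv(out / "m6a_clusters.tsv", sep="\t")
    result.gene_clusters.rename("gene_cluster").to_csv(out / "gene_clusters.tsv", sep="\t")
    result.scores.table.to_csv(out / "scores.tsv", sep="\t")
    result.deg_table.to_csv(out / "deg.tsv", sep="\t")
    result.cox_table.to_csv(out / "cox_screen.tsv", sep="\t")
    result.alluvial.to_csv(out / "alluvial.tsv", sep="\t", index=False)
    if result.tmb is not None:
        result.tmb.to_csv(out / "tmb.tsv", sep="\t")
    if result.associations is not None:
        result.associations.to_csv(out / "associations.tsv", sep="\t", index=False)
    if result.table1 is not None:
        result.table1.to_csv(out / "table1.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    (out / "report.md").write_text(make_report(result))
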