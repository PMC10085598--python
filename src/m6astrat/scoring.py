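"""The per-sample m6A score and its downstream associations.

The score is built from the prognostic gene signature: genes are z-scored
across samples, a PCA is run with samples as observations, and each
sample's score is the sum of its projections on the first two principal
components.  The PC signs are fixed so that each component correlates
non-negatively with the mean z-scored signature expression, which makes the
high/low grouping reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from m6astrat.assoc_stats import rank_tests, spearman
from m6astrat.consensus_cluster import ConsensusResult, consensus_cluster
from m6astrat.io_core import ClinicalTable, ExpressionMatrix, RegulatorPanel
from m6astrat.survival import choose_cutpoint, cox_fit

logger = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Per-sample PC projections, score = PC1 + PC2, and high/low group."""

    table: pd.DataFrame  # columns: pc1, pc2, m6a_score, group
    genes_used: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # genes x 2
    threshold: float
    cut_method: str


def m6a_score(expr: ExpressionMatrix, prognostic_genes: list[str],
              times=None, events=None, cut_method: str = "median") -> ScoreTable:
    """Compute the PCA-based m6A score and the high/low stratification.

    Requires at least 3 signature genes present and 3 samples.  Zero-
    variance genes are dropped with a warning; if the signature matrix has
    rank < 2 the second component is zero and the score equals the PC1
    projection.  The cut method defaults to the score median; ``maxstat``
    needs ``times``/``events``.
    """
    sub = expr.subset_genes(prognostic_genes)
    V = sub.values.to_numpy(dtype=float)
    sds = V.std(axis=1, ddof=1)
    keep = sds > 0
    if (~keep).any():
        logger.warning("m6a_score: dropped %d zero-variance genes", int((~keep).sum()))
    V = V[keep]
    genes = [g for g, k in zip(sub.gene_ids, keep) if k]
    if len(genes) < 3 or V.shape[1] < 3:
        raise ValueError("need >=3 signature genes and >=3 samples")

    center = V.mean(axis=1)
    scale = V.std(axis=1, ddof=1)
    Z = (V - center[:, None]) / scale[:, None]   # genes x samples, z-scored rows

    # PCA with samples as observations: SVD of the samples x genes matrix
    U, S, Vt = np.linalg.svd(Z.T, full_matrices=False)
    proj = U * S                                  # samples x components
    mean_sig = Z.mean(axis=0)                     # per-sample mean signature level

    n_comp = int(np.sum(S > 1e-10 * S[0])) if S.size else 0
    pcs = np.zeros((Z.shape[1], 2))
    load = np.zeros((len(genes), 2))
    for c in range(min(2, n_comp)):
        v = proj[:, c]
        orient = np.dot(v, mean_sig)
        if orient == 0:
            orient = Vt[c, 0] if Vt[c, 0] != 0 else 1.0  # ties: positive first loading
        sign = 1.0 if orient >= 0 else -1.0
        pcs[:, c] = sign * v
        load[:, c] = sign * Vt[c]
    if n_comp < 2:
        logger.warning("m6a_score: signature matrix has rank < 2; PC2 set to 0")

    score = pcs[:, 0] + pcs[:, 1]
    if cut_method == "maxstat":
        if times is None or events is None:
            raise ValueError("maxstat cutpoint needs survival data")
        thr, groups = choose_cutpoint(score, times, events, method="maxstat")
    else:
        thr = float(np.median(score))
        groups = np.where(score > thr, "high", "low")

    table = pd.DataFrame({"pc1": pcs[:, 0], "pc2": pcs[:, 1],
                          "m6a_score": score, "group": groups},
                         index=pd.Index(sub.sample_ids, name="sample_id"))
    return ScoreTable(table, genes, center, scale, load, thr, cut_method)


def score_associations(scores: ScoreTable, tmb: pd.Series | None = None,
                       marker_expr: pd.DataFrame | None = None,
                       immune_scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Associations of the score with TMB, marker genes and immune scores.

    Spearman rho + p for score vs TMB and vs each immune-cell enrichment
    row; two-group Wilcoxon rank-sum for each marker gene between the
    high and low score groups.
    """
    st = scores.table
    rows = []
    if tmb is not None:
        common = st.index.intersection(tmb.index)
        if len(common) < 3:
            raise ValueError("need >=3 paired score/TMB observations")
        rho, p = spearman(st.loc[common, "m6a_score"], tmb.loc[common])
        rows.append(("tmb", "spearman", rho, p))
    if immune_scores is not None:
        common = st.index.intersection(immune_scores.columns)
        for set_name, vals in immune_scores.loc[:, common].iterrows():
            rho, p = spearman(st.loc[common, "m6a_score"], vals)
            rows.append((str(set_name), "spearman", rho, p))
    if marker_expr is not None:
        common = st.index.intersection(marker_expr.columns)
        grp = st.loc[common, "group"].to_numpy()
        for gene, vals in marker_expr.loc[:, common].iterrows():
            stat, p = rank_tests(vals.to_numpy(), grp, kind="wilcoxon2")
            rows.append((str(gene), "wilcoxon_high_vs_low", stat, p))
    return pd.DataFrame(rows, columns=["feature", "test", "statistic", "p"])


def regulator_network(expr: ExpressionMatrix, clinical: ClinicalTable,
                      panel: RegulatorPanel, rho_min: float = 0.3,
                      edge_p: float = 0.05, node_p: float = 0.05) -> dict:
    """Regulator prognostic network: per-gene Cox direction and
    co-expression edges.

    Nodes carry role, univariate Cox HR/p and a risk/favorable direction
    label (HR > 1 is risk).  Edges connect regulator pairs with
    |Spearman rho| >= rho_min and p < edge_p, recorded once per pair.
    """
    sub = expr.subset_genes(panel.genes)
    clin = clinical.aligned(sub.sample_ids)
    known = clin["os_event"].isin([0, 1]) & clin["os_time"].notna()
    times = clin.loc[known, "os_time"].to_numpy()
    events = clin.loc[known, "os_event"].to_numpy().astype(int)
    cols = np.array(sub.sample_ids)[known.to_numpy()]

    nodes = []
    for gene in sub.gene_ids:
        x = sub.values.loc[gene, cols].to_numpy(dtype=float)
        if x.std() == 0:
            nodes.append((gene, panel.roles[gene], np.nan, np.nan, "na"))
            continue
        res = cox_fit(times, events, (x - x.mean()) / x.std())
        direction = "risk" if res.hr[0] > 1 else "favorable"
        nodes.append((gene, panel.roles[gene], float(res.hr[0]),
                      float(res.p_value[0]), direction))
    node_df = pd.DataFrame(nodes, columns=["gene", "role", "hr", "p", "direction"])

    edges = []
    for ga, gb in combinations(sub.gene_ids, 2):
        rho, p = spearman(sub.values.loc[ga], sub.values.loc[gb])
        if abs(rho) >= rho_min and p < edge_p:
            edges.append((ga, gb, rho, p))
    edge_df = pd.DataFrame(edges, columns=["gene_a", "gene_b", "rho", "p"])
    return {"nodes": node_df, "edges": edge_df}


def gene_cluster_assign(expr: ExpressionMatrix, prognostic_genes: list[str],
                        k: int, reps: int = 250, p_item: float = 0.8,
                        seed: int = 0) -> tuple[np.ndarray, ConsensusResult]:
    """Consensus-cluster the patients on the prognostic-gene submatrix.

    Returns the patient labels at the requested (pinned) k together with the
    full consensus result for auditing the model-selection evidence.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sub = expr.subset_genes(prognostic_genes)
    k_max = max(k + 2, 4)
    res = consensus_cluster(sub, range(2, k_max + 1), reps=reps,
                            p_item=p_item, seed=seed)
    return res.labels[k], res
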