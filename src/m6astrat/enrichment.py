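"""Single-sample enrichment scoring and immune-microenvironment summaries.

Implements the ssGSEA running-sum statistic per sample, ESTIMATE-style
immune/stromal scoring with the published cosine purity transform, and a
signature-matrix deconvolution (non-negative least squares, or nu-SVR in the
style of the support-vector deconvolution methods).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.svm import NuSVR

from m6astrat.io_core import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

SSGSEA_ALPHA = 0.25

# Published coefficients of the purity transform:
# purity = cos(0.6049872018 + 0.0001467884 * ESTIMATE score)
_PURITY_A = 0.6049872018
_PURITY_B = 0.0001467884


@dataclass
class EnrichmentScores:
    """Gene set x sample enrichment score matrix."""

    scores: pd.DataFrame
    normalized: bool
    alpha: float


@dataclass
class EstimateScores:
    """Per-sample immune, stromal, combined score and cosine-formula purity.

    ``estimate_score`` is exactly ``immune_score + stromal_score``; the raw
    sum is reported alongside the purity transform because the two move in
    opposite directions (a higher combined score means lower purity).
    """

    table: pd.DataFrame  # columns: immune_score, stromal_score, estimate_score, tumor_purity


def _sample_es(order: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """ssGSEA running sum for one sample.

    ``order`` are gene indices sorted by descending expression.  Ranks are
    centered so extreme genes (top or bottom of the profile) carry the
    largest |rank|; the in-set walk steps by |rank|^alpha normalized over
    the set, the out-of-set walk by 1/(N - set size), and the score is the
    sum of the running differences.  The symmetric weighting keeps the
    expected score of a random set at zero and focuses the statistic on
    concordantly up- or down-ranked sets.
    """
    N = order.size
    ranks = np.arange(N, 0, -1, dtype=float) - (N + 1) / 2.0  # signed, top > 0
    members = in_set[order]
    w = np.where(members, np.abs(ranks) ** alpha, 0.0)
    denom_in = w.sum()
    if denom_in == 0:  # every member sits exactly mid-profile
        w = members.astype(float)
        denom_in = w.sum()
    n_out = N - int(members.sum())
    p_in = np.cumsum(w) / denom_in
    p_out = np.cumsum(np.where(members, 0.0, 1.0)) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea(expr: ExpressionMatrix, sets: GeneSetCollection,
           alpha: float = SSGSEA_ALPHA,
           min_max_normalize: bool = False) -> EnrichmentScores:
    """Single-sample gene set enrichment over all sets and samples.

    Genes are ranked per sample by descending expression with ties broken by
    the stable gene order of the matrix.  Sets with no gene in the matrix
    are skipped with a warning; a set covering every gene is an error (the
    out-of-set walk is undefined).  Optional per-set min-max normalization
    maps each set's scores onto [0, 1] across samples.
    """
    values = expr.values.to_numpy()
    genes = np.array(expr.gene_ids)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes, n_samples = values.shape

    # stable descending sort: argsort of -expression keeps gene order on ties
    orders = np.argsort(-values, axis=0, kind="stable")

    rows = []
    names = []
    for name in sets.names():
        members = [g for g in sets[name] if g in gene_pos]
        dropped = len(sets[name]) - len(members)
        if dropped:
            logger.info("ssgsea: set %s: %d genes absent from matrix", name, dropped)
        if not members:
            logger.warning("ssgsea: set %s has no genes in the matrix; skipped", name)
            continue
        if len(members) >= n_genes:
            raise ValueError(f"gene set {name!r} covers every gene; ES undefined")
        in_set = np.zeros(n_genes, dtype=bool)
        in_set[[gene_pos[g] for g in members]] = True
        rows.append([_sample_es(orders[:, j], in_set, alpha) for j in range(n_samples)])
        names.append(name)

    scores = pd.DataFrame(rows, index=names, columns=expr.sample_ids)
    if min_max_normalize:
        rng_ = scores.max(axis=1) - scores.min(axis=1)
        rng_ = rng_.replace(0.0, 1.0)
        scores = scores.sub(scores.min(axis=1), axis=0).div(rng_, axis=0)
    return EnrichmentScores(scores, normalized=min_max_normalize, alpha=alpha)


def estimate_scores(expr: ExpressionMatrix, immune_set: list[str],
                    stromal_set: list[str], alpha: float = SSGSEA_ALPHA) -> EstimateScores:
    """Immune and stromal signature scores with the cosine purity transform.

    Both scores are unnormalized ssGSEA enrichment scores of the two
    signatures; their sum is the combined score entering
    ``cos(0.6049872018 + 0.0001467884 * score)``.
    """
    sets = GeneSetCollection({"immune": list(dict.fromkeys(immune_set)),
                              "stromal": list(dict.fromkeys(stromal_set))})
    es = ssgsea(expr, sets, alpha=alpha, min_max_normalize=False)
    if set(es.scores.index) != {"immune", "stromal"}:
        raise ValueError("immune or stromal signature has no overlap with the matrix")
    immune = es.scores.loc["immune"]
    stromal = es.scores.loc["stromal"]
    total = immune + stromal
    purity = np.cos(_PURITY_A + _PURITY_B * total)
    table = pd.DataFrame({
        "immune_score": immune, "stromal_score": stromal,
        "estimate_score": total, "tumor_purity": purity,
    })
    table.index.name = "sample_id"
    return EstimateScores(table)


def deconvolve(mixture: ExpressionMatrix, signature: pd.DataFrame,
               mode: str = "nnls") -> pd.DataFrame:
    """Estimate immune cell-type fractions from bulk expression.

    ``signature`` is a genes x cell-types reference matrix.  ``nnls`` solves
    a non-negative least squares per sample; ``svr`` fits nu-SVR over
    nu in {0.25, 0.5, 0.75}, keeps the best fit by RMSE, and clips negative
    coefficients.  Fractions are normalized to sum to one per sample.
    """
    common = [g for g in signature.index if g in set(mixture.gene_ids)]
    if not common:
        raise ValueError("signature genes do not overlap the mixture matrix")
    if signature.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    S = signature.loc[common].to_numpy(dtype=float)
    X = mixture.values.loc[common].to_numpy(dtype=float)

    # identical signature columns cannot be told apart; warn and let the
    # deterministic solver order put the weight on the lowest index
    for i in range(S.shape[1]):
        for j in range(i + 1, S.shape[1]):
            if np.allclose(S[:, i], S[:, j]):
                logger.warning("deconvolve: signature columns %d and %d identical; "
                               "split is arbitrary but deterministic", i, j)

    fractions = np.zeros((X.shape[1], S.shape[1]))
    for j in range(X.shape[1]):
        y = X[:, j]
        if mode == "nnls":
            coef, _ = nnls(S, y)
        elif mode == "svr":
            best, best_rmse = None, np.inf
            for nu in (0.25, 0.5, 0.75):
                svr = NuSVR(kernel="linear", nu=nu, C=1.0)
                svr.fit(S, y)
                pred = svr.predict(S)
                rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
                if rmse < best_rmse:
                    best, best_rmse = svr.coef_.ravel().copy(), rmse
            coef = np.clip(best, 0.0, None)
        else:
            raise ValueError(f"unknown deconvolution mode {mode!r}")
        total = coef.sum()
        fractions[j] = coef / total if total > 0 else np.full_like(coef, 1.0 / coef.size)

    out = pd.DataFrame(fractions, index=mixture.sample_ids, columns=list(signature.columns))
    out.index.name = "sample_id"
    return out
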