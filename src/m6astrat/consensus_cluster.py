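"""Resampling consensus clustering with CDF / delta-area model selection.

The scheme follows the classic subsampled-consensus recipe: repeatedly
subsample a fraction ``p_item`` of samples, run a base clusterer on each
subsample, and record for every sample pair how often it co-clusters among
the runs where it was co-sampled.  The consensus matrix entries act as a
co-clustering probability; the empirical CDF of its upper triangle, and the
relative gain in area under that CDF as k grows, guide the choice of k.

One hierarchical tree is built per subsample and cut at every k in the
range, so the subsampling noise is shared across k — the behavior of the
reference consensus-clustering implementations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from m6astrat.io_core import ExpressionMatrix

logger = logging.getLogger(__name__)

CDF_GRID = np.linspace(0.0, 1.0, 101)


class DegenerateInputError(ValueError):
    """Raised when the expression submatrix cannot be clustered."""


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, labels, CDF curves and the chosen k."""

    sample_ids: list[str]
    consensus: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]
    cdf: dict[int, np.ndarray]
    area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    params: dict = field(default_factory=dict)
    n_never_cosampled: int = 0

    def labels_series(self, k: int) -> pd.Series:
        return pd.Series(self.labels[k], index=self.sample_ids, name=f"k{k}")


def _pearson_distance(columns: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson correlation distance between sample columns."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(columns.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return squareform(dist, checks=False)


def base_cluster(matrix: np.ndarray | ExpressionMatrix, k: int,
                 method: str = "hierarchical-pearson-average",
                 seed: int | None = 0) -> np.ndarray:
    """Cluster the samples (columns) of a genes x samples matrix into k groups.

    ``hierarchical-pearson-average`` uses 1 - Pearson correlation distance
    between sample columns with average linkage, cut at k; ``kmeans-euclid``
    runs k-means on the sample vectors.  Deterministic given the seed.
    """
    values = matrix.values.to_numpy() if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix)
    n = values.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    if method == "hierarchical-pearson-average":
        Z = linkage(_pearson_distance(values), method="average")
        return fcluster(Z, t=k, criterion="maxclust") - 1
    if method == "kmeans-euclid":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(values.T)
    raise ValueError(f"unknown base clustering method {method!r}")


def consensus_cluster(expr_subset: ExpressionMatrix,
                      k_range: range | list[int] = range(2, 10),
                      reps: int = 1000, p_item: float = 0.8,
                      seed: int = 0,
                      method: str = "hierarchical-pearson-average",
                      delta_area_threshold: float = 0.1) -> ConsensusResult:
    """Subsampled consensus clustering of samples on a gene submatrix.

    For each k, ``M_k(i, j)`` is the fraction of subsamples containing both
    i and j in which they landed in the same base cluster.  Pairs never
    co-sampled (vanishingly rare at the defaults) get consensus 0 and are
    counted in the log.  Final labels cut an average-linkage tree on the
    ``1 - M_k`` distance at k.
    """
    values = expr_subset.values.to_numpy()
    n_genes, n = values.shape
    ks = sorted(set(int(k) for k in k_range))
    if n_genes < 2:
        raise DegenerateInputError("need at least 2 genes to cluster samples")
    if np.allclose(values.var(axis=1), 0.0):
        raise DegenerateInputError("constant expression in every gene")
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range {ks[0]}..{ks[-1]} outside [2, {n - 1}]")
    if not (0 < p_item <= 1):
        raise ValueError("p_item must lie in (0, 1]")
    if n < ks[-1] + 1:
        raise ValueError("need at least max(k_range)+1 samples")

    rng = np.random.default_rng(seed)
    m = math.ceil(p_item * n)
    co_cluster = {k: np.zeros((n, n)) for k in ks}
    co_sampled = np.zeros((n, n))

    for rep in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
        sub = values[:, idx]
        ix = np.ix_(idx, idx)
        co_sampled[ix] += 1.0
        if method == "hierarchical-pearson-average":
            Z = linkage(_pearson_distance(sub), method="average")
            for k in ks:
                labels = fcluster(Z, t=k, criterion="maxclust")
                same = labels[:, None] == labels[None, :]
                co_cluster[k][ix] += same
        else:
            for k in ks:
                labels = base_cluster(sub, k, method=method,
                                      seed=int(rng.integers(2**31 - 1)))
                same = labels[:, None] == labels[None, :]
                co_cluster[k][ix] += same

    never = (co_sampled == 0)
    np.fill_diagonal(never, False)
    n_never = int(never.sum() // 2)
    if n_never:
        logger.warning("consensus_cluster: %d sample pairs never co-sampled; consensus set to 0",
                       n_never)

    consensus: dict[int, np.ndarray] = {}
    final_labels: dict[int, np.ndarray] = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in ks:
            M = np.where(co_sampled > 0, co_cluster[k] / np.maximum(co_sampled, 1), 0.0)
            np.fill_diagonal(M, 1.0)
            M = (M + M.T) / 2.0
            consensus[k] = M
            Z = linkage(squareform(np.clip(1.0 - M, 0.0, None), checks=False),
                        method="average")
            final_labels[k] = fcluster(Z, t=k, criterion="maxclust") - 1

    cdf, area, delta, chosen = cdf_and_delta_area(consensus, threshold=delta_area_threshold)
    return ConsensusResult(
        sample_ids=expr_subset.sample_ids, consensus=consensus,
        labels=final_labels, cdf=cdf, area=area, delta_area=delta,
        chosen_k=chosen,
        params={"reps": reps, "p_item": p_item, "method": method,
                "seed": seed, "k_range": ks, "delta_area_threshold": delta_area_threshold},
        n_never_cosampled=n_never,
    )


def cdf_and_delta_area(consensus: dict[int, np.ndarray], threshold: float = 0.1,
                       ) -> tuple[dict[int, np.ndarray], dict[int, float], dict[int, float], int]:
    """Empirical CDF of upper-triangle consensus entries on a 101-point grid,
    trapezoid areas, relative area gains, and the advised k.

    delta_area(k_min) is the raw area A_{k_min}; for larger k it is
    (A_k - A_{k-1}) / A_{k-1}.  The advised k is the largest k whose
    delta_area meets the threshold.
    """
    ks = sorted(consensus)
    if len(ks) < 2:
        raise ValueError("need at least 2 values of k")
    cdf: dict[int, np.ndarray] = {}
    area: dict[int, float] = {}
    for k in ks:
        M = consensus[k]
        iu = np.triu_indices(M.shape[0], 1)
        vals = M[iu]
        curve = np.array([(vals <= t).mean() for t in CDF_GRID])
        cdf[k] = curve
        area[k] = float(np.trapezoid(curve, CDF_GRID))
    delta: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = area[k]
        else:
            prev = area[ks[i - 1]]
            delta[k] = (area[k] - prev) / prev if prev > 0 else 0.0
    candidates = [k for k in ks if delta[k] >= threshold]
    chosen = max(candidates) if candidates else ks[0]
    return cdf, area, delta, chosen
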