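"""Moderated differential expression across expression clusters.

Per-gene one-way linear models with empirical-Bayes variance shrinkage:
residual variances are squeezed toward a common prior variance s0^2 with
prior degrees of freedom d0, both estimated in closed form by the method of
moments on log residual variances (the Fisher-z moment equations used by
moderated-statistic pipelines).  The moderated F statistic then carries
(k - 1, d0 + d_g) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats

from m6astrat.io_core import ExpressionMatrix


@dataclass
class DEGResult:
    """Per-gene moderated one-way test results.

    ``table`` columns: mean per group, residual variance ``s2``, moderated
    variance ``s2_post``, moderated F, ``p_value``, BH-adjusted ``p_adj``,
    and one two-sided moderated-t p-value per pairwise contrast.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    groups: list[str]
    p_threshold: float

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["p_value"] < self.p_threshold])

    def significant_per_contrast(self) -> dict[str, list[str]]:
        cols = [c for c in self.table.columns if c.startswith("p_")
                and c not in ("p_value", "p_adj")]
        return {c[2:]: list(self.table.index[self.table[c] < self.p_threshold])
                for c in cols}


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # standard starting value
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def fit_f_dist_moments(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0^2) to residual
    variances ``s2`` with common residual df.

    Uses the moments of log s^2: E[log s^2] and Var[log s^2] are linear in
    digamma/trigamma terms of d/2 and d0/2.  Returns d0 = inf when the
    observed spread is no larger than the sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if e.size > 1 else 0.0
    # spread of log-variances beyond what sampling alone explains
    resid_var = e_var - float(special.polygamma(1, df / 2.0))
    if resid_var > 0:
        d0 = 2.0 * float(_trigamma_inverse(resid_var))
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def moderated_f_test(expr: ExpressionMatrix, labels: pd.Series | dict | np.ndarray,
                     p_threshold: float = 0.01,
                     d0_override: float | None = None) -> DEGResult:
    """Moderated one-way F test of every gene across cluster labels.

    ``labels`` aligns with the matrix samples (a Series indexed by sample
    id, a mapping, or an array in column order).  ``d0_override=0`` disables
    shrinkage and reduces the statistic to the classical one-way ANOVA F.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    if isinstance(labels, pd.Series):
        labels = labels.reindex(expr.sample_ids)
        if labels.isna().any():
            raise ValueError("labels missing for some samples")
        lab = labels.to_numpy()
    else:
        lab = np.asarray(labels)
        if lab.size != len(expr.sample_ids):
            raise ValueError("labels length does not match samples")

    groups = sorted(pd.unique(lab).tolist())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    masks = {g: lab == g for g in groups}
    sizes = {g: int(m.sum()) for g, m in masks.items()}
    if min(sizes.values()) < 2:
        raise ValueError("every group needs at least 2 samples")

    X = expr.values.to_numpy()
    n = X.shape[1]
    k = len(groups)
    df_resid = n - k
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    group_means = np.column_stack([X[:, masks[g]].mean(axis=1) for g in groups])
    grand = X.mean(axis=1)
    ss_between = sum(sizes[g] * (group_means[:, i] - grand) ** 2
                     for i, g in enumerate(groups))
    fitted = np.zeros_like(X)
    for i, g in enumerate(groups):
        fitted[:, masks[g]] = group_means[:, [i]]
    ss_within = ((X - fitted) ** 2).sum(axis=1)
    s2 = ss_within / df_resid
    ms_between = ss_between / (k - 1)

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    else:
        d0, s0_sq = fit_f_dist_moments(s2, df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        f_mod = np.where(s2_post > 0, ms_between / s2_post, 0.0)
    f_mod = np.nan_to_num(f_mod, nan=0.0)
    if np.isinf(df_total):
        p = stats.chi2.sf(f_mod * (k - 1), k - 1)
    else:
        p = stats.f.sf(f_mod, k - 1, df_total)
    p = np.where(f_mod <= 0, 1.0, p)

    table = pd.DataFrame(index=pd.Index(expr.gene_ids, name="gene"))
    for i, g in enumerate(groups):
        table[f"mean_{g}"] = group_means[:, i]
    table["s2"] = s2
    table["s2_post"] = s2_post
    table["f_moderated"] = f_mod
    table["p_value"] = p
    table["p_adj"] = _bh_adjust(p)

    for ga, gb in combinations(groups, 2):
        diff = table[f"mean_{ga}"] - table[f"mean_{gb}"]
        se = np.sqrt(s2_post * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, diff / se, 0.0)
        if np.isinf(df_total):
            pc = 2.0 * stats.norm.sf(np.abs(t))
        else:
            pc = 2.0 * stats.t.sf(np.abs(t), df_total)
        table[f"p_{ga}_vs_{gb}"] = np.where(se > 0, pc, 1.0)

    return DEGResult(table, d0=d0, s0_sq=s0_sq, groups=[str(g) for g in groups],
                     p_threshold=p_threshold)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def venn_intersect(sig_sets: list[list[str]]) -> list[str]:
    """Exact intersection of gene lists, preserving the order of the first."""
    if len(sig_sets) < 2:
        raise ValueError("need at least 2 sets to intersect")
    common = set(sig_sets[0])
    for s in sig_sets[1:]:
        common &= set(s)
    return [g for g in sig_sets[0] if g in common]
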