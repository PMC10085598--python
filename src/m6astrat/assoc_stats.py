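"""Statistical kernels shared across the pipeline, and the two-cohort
clinical comparison table.

Percentages in the comparison table are computed over the full cohort size,
with unknowns as their own row; categorical p-values are Pearson chi-square
without continuity correction on the known-category counts, and the age
comparison is a chi-square on the <=60 / >60 dichotomy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from m6astrat.io_core import ClinicalTable, UNKNOWN

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """r x c nonnegative integer counts with labels."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError("need at least 2 rows and 2 columns")


def chisq_test(table: ContingencyTable | np.ndarray, yates: bool = False,
               ) -> tuple[float, int, float]:
    """Pearson chi-square test of independence; optional Yates correction
    (2x2 only).  Errors on a zero marginal."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=float)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=yates)
    return float(stat), int(df), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with the
    t-approximation p-value on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def rank_tests(values, groups, kind: str = "wilcoxon2") -> tuple[float, float]:
    """Two-sided rank tests with tie correction.

    ``wilcoxon2``: Mann-Whitney/Wilcoxon rank-sum, normal approximation, no
    continuity correction (so identical group distributions give p = 1).
    ``kruskal``: Kruskal-Wallis chi-square approximation for >=2 groups.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if np.all(values == values[0]):
        logger.warning("rank_tests: all values identical; p set to 1")
        return 0.0, 1.0
    if kind == "wilcoxon2":
        if len(labels) != 2:
            raise ValueError("wilcoxon2 needs exactly 2 groups")
        a = values[groups == labels[0]]
        b = values[groups == labels[1]]
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 use_continuity=False, method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if kind == "kruskal":
        if len(labels) < 2:
            raise ValueError("kruskal needs at least 2 groups")
        samples = [values[groups == g] for g in labels]
        res = stats.kruskal(*samples)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown rank test {kind!r}")


def _fmt_count(n: int, total: int) -> str:
    return f"{n}({100.0 * n / total:.1f}%)"


def _categorical_block(a: pd.Series, b: pd.Series, categories: list[str],
                       n_a: int, n_b: int) -> tuple[list[dict], float | None]:
    rows = []
    counts_a, counts_b = [], []
    for cat in categories:
        ca = int((a == cat).sum())
        cb = int((b == cat).sum())
        rows.append({"level": cat, "cohort_a": _fmt_count(ca, n_a),
                     "cohort_b": _fmt_count(cb, n_b)})
        counts_a.append(ca)
        counts_b.append(cb)
    ua, ub = int((a == UNKNOWN).sum()), int((b == UNKNOWN).sum())
    if ua or ub:
        rows.append({"level": "Unknown", "cohort_a": _fmt_count(ua, n_a),
                     "cohort_b": _fmt_count(ub, n_b)})
    table = np.array([counts_a, counts_b])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    p = None
    if table.shape[1] >= 2 and (table.sum(axis=1) > 0).all():
        _, _, p = chisq_test(table)
    return rows, p


def cohort_comparison(clin_a: ClinicalTable, clin_b: ClinicalTable,
                      age_cut: float = 60.0) -> pd.DataFrame:
    """Two-cohort clinical characteristics table with chi-square p-values.

    Continuous variables are reported as ``median [min, max]``; the age
    p-value comes from the chi-square on the <=cut / >cut dichotomy, the
    survival-time comparison from a two-sided rank-sum test.
    """
    A, B = clin_a.data, clin_b.data
    n_a, n_b = len(A), len(B)
    out_rows: list[dict] = []

    def median_range(s: pd.Series) -> str:
        s = s.dropna()
        if s.empty:
            return "NA"
        return f"{s.median():.1f} [{s.min():.1f}, {s.max():.1f}]"

    # age: median [min,max] + dichotomized counts and chi-square
    age_a, age_b = A["age"], B["age"]
    le_a, gt_a = int((age_a <= age_cut).sum()), int((age_a > age_cut).sum())
    le_b, gt_b = int((age_b <= age_cut).sum()), int((age_b > age_cut).sum())
    _, _, p_age = chisq_test(np.array([[le_a, gt_a], [le_b, gt_b]]))
    out_rows.append({"variable": "age", "level": "median [min, max]",
                     "cohort_a": median_range(age_a), "cohort_b": median_range(age_b),
                     "p": p_age})
    out_rows.append({"variable": "age", "level": f"<={age_cut:g}",
                     "cohort_a": _fmt_count(le_a, n_a), "cohort_b": _fmt_count(le_b, n_b), "p": None})
    out_rows.append({"variable": "age", "level": f">{age_cut:g}",
                     "cohort_a": _fmt_count(gt_a, n_a), "cohort_b": _fmt_count(gt_b, n_b), "p": None})
    una, unb = int(age_a.isna().sum()), int(age_b.isna().sum())
    if una or unb:
        out_rows.append({"variable": "age", "level": "Unknown",
                         "cohort_a": _fmt_count(una, n_a), "cohort_b": _fmt_count(unb, n_b),
                         "p": None})

    cat_levels = {
        "gender": ["male", "female"],
        "t_stage": ["T1", "T2", "T3", "T4"],
        "n_stage": ["N0", "N1", "N2", "N3"],
        "m_stage": ["M0", "M1"],
        "tnm_stage": ["I", "II", "III", "IV"],
        "grade": ["G1", "G2", "G3"],
    }
    # OS status from the event indicator
    ev_a = A["os_event"].map({0: "alive", 1: "dead"}).fillna(UNKNOWN)
    ev_b = B["os_event"].map({0: "alive", 1: "dead"}).fillna(UNKNOWN)
    rows, p = _categorical_block(ev_a, ev_b, ["alive", "dead"], n_a, n_b)
    for i, r in enumerate(rows):
        out_rows.append({"variable": "os_status", **r, "p": p if i == 0 else None})

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ta = A["os_time"].dropna()
        tb = B["os_time"].dropna()
        if len(ta) and len(tb):
            vals = np.concatenate([ta, tb])
            grp = np.array(["a"] * len(ta) + ["b"] * len(tb))
            _, p_time = rank_tests(vals, grp, kind="wilcoxon2")
        else:
            p_time = None
    out_rows.append({"variable": "os_time", "level": "median [min, max]",
                     "cohort_a": median_range(A["os_time"]),
                     "cohort_b": median_range(B["os_time"]), "p": p_time})

    for var, levels in cat_levels.items():
        a = A[var].fillna(UNKNOWN)
        b = B[var].fillna(UNKNOWN)
        if (a == UNKNOWN).all() or (b == UNKNOWN).all():
            # one cohort lacks the variable entirely: report counts, no test
            rows, _ = _categorical_block(a, b, levels, n_a, n_b)
            p = None
        else:
            rows, p = _categorical_block(a, b, levels, n_a, n_b)
        for i, r in enumerate(rows):
            out_rows.append({"variable": var, **r, "p": p if i == 0 else None})

    return pd.DataFrame(out_rows, columns=["variable", "level", "cohort_a", "cohort_b", "p"])
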