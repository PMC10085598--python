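import numpy as np
import pandas as pd
import pytest
from scipy import stats

from m6astrat.assoc_stats import (ContingencyTable, chisq_test,
                                  cohort_comparison, rank_tests, spearman)
from m6astrat.io_core import ClinicalTable, CLINICAL_COLUMNS, UNKNOWN


# ------------------------------------------------------------------ chi-square

def test_identical_proportions_give_null():
    stat, df, p = chisq_test(np.array([[30, 70], [60, 140]]))
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chisq_zero_marginal_errors():
    with pytest.raises(ValueError):
        chisq_test(np.array([[0, 0], [5, 5]]))


def test_chisq_matches_two_proportion_z_test():
    """Uncorrected 2x2 chi-square equals the squared z-test of proportions."""
    table = np.array([[40, 60], [55, 45]])
    stat, _, _ = chisq_test(table)
    n1, n2 = table.sum(axis=1)
    p1, p2 = table[0, 0] / n1, table[1, 0] / n2
    pp = table[:, 0].sum() / table.sum()
    z = (p1 - p2) / np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
    assert stat == pytest.approx(z ** 2, abs=1e-10)


def test_chisq_invariant_to_permutations():
    table = np.array([[12, 7, 30], [25, 14, 9]])
    stat, df, p = chisq_test(table)
    stat2, df2, p2 = chisq_test(table[::-1, ::-1])
    assert (stat, df, p) == (pytest.approx(stat2), df2, pytest.approx(p2))


def test_chisq_matches_monte_carlo_null():
    """The chi-square p-value on a 3x2 table agrees with a multinomial
    Monte-Carlo null within 3 MC standard errors."""
    table = np.array([[18, 12], [10, 20], [14, 16]])
    stat, df, p = chisq_test(table)
    rng = np.random.default_rng(0)
    n = table.sum()
    probs = np.outer(table.sum(axis=1) / n, table.sum(axis=0) / n).ravel()
    draws = rng.multinomial(n, probs, size=100_000).reshape(-1, 3, 2).astype(float)
    # each draw's statistic uses its own margins
    row = draws.sum(axis=2, keepdims=True)
    col = draws.sum(axis=1, keepdims=True)
    E_mc = row * col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(E_mc > 0, (draws - E_mc) ** 2 / E_mc, 0.0)
    stats_mc = terms.sum(axis=(1, 2))
    exceed = (stats_mc >= stat - 1e-12).mean()
    se = np.sqrt(exceed * (1 - exceed) / 100_000)
    assert abs(p - exceed) < 3 * se + 0.005


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(np.array([[1, -2], [3, 4]]), ["a", "b"], ["x", "y"])
    with pytest.raises(ValueError):
        ContingencyTable(np.array([[1, 2]]), ["a"], ["x", "y"])


# ------------------------------------------------------------------ Spearman

def test_spearman_monotone_and_reverse():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert spearman(x, x ** 2)[0] == pytest.approx(1.0)
    assert spearman(x, -x)[0] == pytest.approx(-1.0)


def test_spearman_ties_equal_pearson_of_average_ranks():
    rng = np.random.default_rng(1)
    x = rng.integers(0, 4, 60).astype(float)   # heavy ties
    y = rng.integers(0, 3, 60).astype(float)
    rho, _ = spearman(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)


def test_spearman_validation():
    with pytest.raises(ValueError):
        spearman([1, 2], [3, 4])
    with pytest.raises(ValueError):
        spearman([1, 1, 1], [1, 2, 3])


# ------------------------------------------------------------------ rank tests

def test_identical_multisets_give_p_one():
    vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    grp = np.array(["a"] * 3 + ["b"] * 3)
    _, p = rank_tests(vals, grp, kind="wilcoxon2")
    assert p == pytest.approx(1.0)


def test_all_identical_values_warn_p_one():
    _, p = rank_tests(np.ones(10), ["a"] * 5 + ["b"] * 5)
    assert p == 1.0


def test_kruskal_two_groups_matches_wilcoxon():
    rng = np.random.default_rng(2)
    vals = rng.normal(size=200)  # continuous: no ties
    grp = np.array(["a"] * 100 + ["b"] * 100)
    _, p_w = rank_tests(vals, grp, kind="wilcoxon2")
    _, p_k = rank_tests(vals, grp, kind="kruskal")
    assert p_w == pytest.approx(p_k, abs=1e-6)


def test_shift_alternative_power():
    """1-SD shift at n=50/50 is detected with power > 0.9 at alpha=0.05."""
    rng = np.random.default_rng(3)
    rejections = 0
    n_sim = 500
    for _ in range(n_sim):
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        _, p = rank_tests(np.concatenate([a, b]),
                         ["a"] * 50 + ["b"] * 50, kind="wilcoxon2")
        rejections += p < 0.05
    assert rejections / n_sim > 0.9


# ------------------------------------------------------------- cohort tables

def _clinical_from_counts(n, male, female, alive, dead, age_le, age_gt,
                          age_unknown=0, os_unknown=0):
    """Build a clinical table realizing given marginal counts; joint structure
    is irrelevant for the per-variable comparisons."""
    df = pd.DataFrame({"sample_id": [f"p{i}" for i in range(n)]})
    df["gender"] = ["male"] * male + ["female"] * female + [UNKNOWN] * (n - male - female)
    ev = [0] * alive + [1] * dead + [np.nan] * os_unknown
    df["os_event"] = ev + [np.nan] * (n - len(ev))
    ages = [50] * age_le + [70] * age_gt + [np.nan] * age_unknown
    df["age"] = ages + [np.nan] * (n - len(ages))
    df["os_time"] = 10.0
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = UNKNOWN
    return ClinicalTable(df[CLINICAL_COLUMNS])


@pytest.fixture(scope="module")
def printed_cohorts():
    """Two cohorts with the published stomach-cancer cohort margins."""
    a = _clinical_from_counts(350, male=226, female=124, alive=204, dead=145,
                              age_le=117, age_gt=230, age_unknown=3, os_unknown=1)
    b = _clinical_from_counts(433, male=296, female=137, alive=224, dead=209,
                              age_le=194, age_gt=239)
    return a, b


def test_cohort_percentages_over_full_n(printed_cohorts):
    a, b = printed_cohorts
    report = cohort_comparison(a, b)
    male = report[(report["variable"] == "gender") & (report["level"] == "male")]
    assert male["cohort_a"].iloc[0] == "226(64.6%)"
    assert male["cohort_b"].iloc[0] == "296(68.4%)"
    le60 = report[(report["variable"] == "age") & (report["level"] == "<=60")]
    assert le60["cohort_a"].iloc[0] == "117(33.4%)"


def test_cohort_comparison_pvalues(printed_cohorts):
    a, b = printed_cohorts
    report = cohort_comparison(a, b)
    p = report.dropna(subset=["p"]).set_index("variable")["p"]
    assert p["gender"] == pytest.approx(0.263, abs=1e-3)
    assert p["os_status"] == pytest.approx(0.061, abs=1e-3)
    assert round(p["age"], 3) == 0.002


def test_cohort_compared_with_itself_is_null(printed_cohorts):
    a, _ = printed_cohorts
    report = cohort_comparison(a, a)
    for val in report.dropna(subset=["p"])["p"]:
        assert val == pytest.approx(1.0)
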