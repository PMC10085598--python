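import numpy as np
import pandas as pd
import pytest

from m6astrat.survival import (choose_cutpoint, cox_fit, cox_screen,
                               km_estimate, logrank_test)


# ------------------------------------------------------------------ KM

def test_km_hand_product_limit():
    curve = km_estimate([1, 2, 3], [1, 1, 0])
    assert np.allclose(curve.survival, [2 / 3, 1 / 3, 1 / 3])
    assert curve.median == 2.0


def test_km_all_censored():
    curve = km_estimate([1, 2, 3], [0, 0, 0])
    assert np.allclose(curve.survival, 1.0)
    assert curve.median is None


def test_km_duplication_invariance():
    t = [2.0, 3.0, 5.0, 7.0]
    e = [1, 0, 1, 1]
    a = km_estimate(t, e)
    b = km_estimate(t + t, e + e)
    assert np.allclose(a.survival, b.survival)
    assert np.array_equal(a.times, b.times)


def test_km_equals_empirical_without_censoring():
    rng = np.random.default_rng(0)
    t = rng.exponential(size=50)
    curve = km_estimate(t, np.ones(50, dtype=int))
    for ti, si in zip(curve.times, curve.survival):
        assert si == pytest.approx((t > ti).mean())


def test_km_negative_time_errors():
    with pytest.raises(ValueError):
        km_estimate([-1, 2], [1, 1])


# ------------------------------------------------------------------ log-rank

def test_logrank_identical_groups_is_null():
    t = [1, 2, 3, 4, 5, 6]
    e = [1, 0, 1, 1, 0, 1]
    res = logrank_test(t + t, e + e, ["a"] * 6 + ["b"] * 6)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_single_group_errors():
    with pytest.raises(ValueError):
        logrank_test([1, 2], [1, 1], ["a", "a"])


def test_logrank_matches_permutation_oracle():
    """Two-group log-rank p on an n=12 toy agrees with the exact permutation
    distribution of the statistic within Monte-Carlo error."""
    rng = np.random.default_rng(11)
    times = np.array([3, 5, 7, 2, 8, 4, 9, 12, 6, 10, 1, 11], dtype=float)
    events = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1, 1, 0])
    groups = np.array(["a"] * 6 + ["b"] * 6)
    obs = logrank_test(times, events, groups)
    n_perm = 10_000
    exceed = 0
    for _ in range(n_perm):
        exceed += logrank_test(times, events, rng.permutation(groups)).statistic \
            >= obs.statistic - 1e-12
    p_perm = exceed / n_perm
    mc_se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
    assert abs(obs.p_value - p_perm) < 3 * mc_se + 0.02


def test_three_group_reduces_to_two_when_groups_merged():
    """Splitting one group into two identical halves leaves the evidence
    against homogeneity essentially unchanged."""
    rng = np.random.default_rng(5)
    t1 = rng.exponential(1.0, 30)
    t2 = rng.exponential(2.5, 30)
    times = np.concatenate([t1, t2])
    events = np.ones(60, dtype=int)
    two = logrank_test(times, events, ["a"] * 30 + ["b"] * 30)
    # duplicate the whole dataset, relabelling group b as b/c halves
    times_d = np.concatenate([times, times])
    events_d = np.concatenate([events, events])
    groups_d = (["a"] * 30 + ["b"] * 30) + (["a"] * 30 + ["c"] * 30)
    three = logrank_test(times_d, events_d, groups_d)
    assert three.df == 2
    # the b and c groups are identical, so the 3-group statistic equals the
    # duplicated 2-group statistic
    two_d = logrank_test(times_d, events_d,
                         ["a"] * 30 + ["b"] * 30 + ["a"] * 30 + ["b"] * 30)
    assert three.statistic == pytest.approx(two_d.statistic, rel=1e-8)


def test_logrank_equals_cox_score_test_without_ties():
    """On tie-free data the 2-group log-rank statistic equals the Cox score
    test at beta=0 up to the hypergeometric n/(n-1) variance factor; with a
    single event per time both reduce to the same sum."""
    rng = np.random.default_rng(9)
    n = 40
    times = rng.uniform(1, 100, n)  # continuous: no ties
    events = rng.integers(0, 2, n)
    events[0] = 1
    x = np.array([0] * 20 + [1] * 20, dtype=float)
    order = np.argsort(times)
    t_s, e_s, x_s = times[order], events[order], x[order]
    U = 0.0
    V = 0.0
    for i in np.nonzero(e_s == 1)[0]:
        risk = t_s >= t_s[i]
        p = x_s[risk].mean()
        U += x_s[i] - p
        V += p * (1 - p)
    score_stat = U ** 2 / V
    lr = logrank_test(times, events, np.where(x > 0, "b", "a"))
    assert lr.statistic == pytest.approx(score_stat, abs=1e-8)


# ------------------------------------------------------------------ Cox

def _sim_cox(n=100, beta=0.7, seed=42, round_ties=True):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-beta * x))
    c = rng.exponential(1.5, size=n)
    times = np.minimum(t, c)
    if round_ties:
        times = np.round(times, 1) + 0.01
    events = (t <= c).astype(int)
    return times, events, x


def test_cox_symmetric_covariate_gives_zero_beta():
    times = np.array([1.0, 2.0, 3.0, 4.0] * 2)
    events = np.array([1, 1, 1, 0] * 2)
    x = np.array([0, 1, 0, 1, 1, 0, 1, 0], dtype=float)
    res = cox_fit(times, events, x)
    assert res.beta[0] == pytest.approx(0.0, abs=1e-8)


def test_cox_matches_reference_implementation():
    """Efron and Breslow fits agree with established survival libraries to
    |dbeta| < 1e-6 on tied data."""
    times, events, x = _sim_cox()
    import warnings
    warnings.filterwarnings("ignore")
    import lifelines
    cf = lifelines.CoxPHFitter()
    cf.fit(pd.DataFrame({"t": times, "e": events, "x": x}), "t", "e",
           fit_options={"precision": 1e-11})
    mine_e = cox_fit(times, events, x, ties="efron")
    assert mine_e.converged
    assert abs(mine_e.beta[0] - cf.params_.iloc[0]) < 1e-6

    from sksurv.linear_model import CoxPHSurvivalAnalysis
    y = np.array([(bool(e), t) for e, t in zip(events, times)],
                 dtype=[("e", bool), ("t", float)])
    ref = CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12, n_iter=200)
    ref.fit(x[:, None], y)
    mine_b = cox_fit(times, events, x, ties="breslow")
    assert abs(mine_b.beta[0] - ref.coef_[0]) < 1e-6


def test_breslow_equals_efron_without_ties():
    times, events, x = _sim_cox(round_ties=False, seed=1)
    a = cox_fit(times, events, x, ties="efron")
    b = cox_fit(times, events, x, ties="breslow")
    assert a.beta[0] == pytest.approx(b.beta[0], abs=1e-10)


def test_cox_constant_covariate_errors():
    with pytest.raises(ValueError, match="constant"):
        cox_fit([1, 2, 3], [1, 1, 0], [2.0, 2.0, 2.0])


def test_cox_perfect_separation_flagged():
    times = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
    events = np.ones(8, dtype=int)
    x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
    res = cox_fit(times, events, x)
    assert not res.converged
    assert abs(res.beta[0]) <= 20.0 + 1e-9


def test_cox_screen_recall_and_fpr(default_cohort):
    """Univariate screen at p<0.01: planted prognostic genes are recovered
    (recall >= 0.9) and noise genes rarely pass (FPR <= 0.02)."""
    co = default_cohort
    tg = co.truth_genes.set_index("gene")
    prognostic = sorted(tg.index[tg["prognostic"]])
    noise = sorted(g for g in tg.index if g.startswith("BG"))[:250]
    clin = co.clinical.data
    tab = cox_screen(co.expression.values.loc[prognostic + noise],
                     clin["os_time"].to_numpy(), clin["os_event"].to_numpy(),
                     p_threshold=0.01)
    hits = set(tab.index[tab["significant"]])
    assert len(hits & set(prognostic)) / len(prognostic) >= 0.9
    assert len(hits & set(noise)) / len(noise) <= 0.02


# ------------------------------------------------------------------ cutpoint

def test_median_cutpoint_splits_evenly():
    rng = np.random.default_rng(2)
    score = rng.normal(size=101)
    t = rng.exponential(size=101)
    thr, labels = choose_cutpoint(score, t, np.ones(101, dtype=int), method="median")
    n_high = (labels == "high").sum()
    assert abs(n_high - 50) <= 1


def test_maxstat_at_least_median_statistic():
    rng = np.random.default_rng(3)
    n = 120
    score = rng.normal(size=n)
    lam = 0.05 * np.exp(1.0 * (score > 0))
    t = rng.exponential(1 / lam)
    e = np.ones(n, dtype=int)
    thr_m, lab_m = choose_cutpoint(score, t, e, method="median")
    thr_x, lab_x = choose_cutpoint(score, t, e, method="maxstat")
    s_med = logrank_test(t, e, lab_m).statistic
    s_max = logrank_test(t, e, lab_x).statistic
    assert s_max >= s_med - 1e-9


def test_maxstat_finds_planted_threshold():
    rng = np.random.default_rng(4)
    n = 400
    score = rng.normal(size=n)
    lam = 0.05 * np.exp(1.5 * (score > 0))
    t = rng.exponential(1 / lam)
    e = np.ones(n, dtype=int)
    thr, _ = choose_cutpoint(score, t, e, method="maxstat")
    assert abs(thr) < 0.1


def test_constant_score_errors():
    with pytest.raises(ValueError):
        choose_cutpoint(np.ones(30), np.arange(1, 31), np.ones(30, dtype=int))
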