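import numpy as np
import pandas as pd
import pytest

from m6astrat.io_core import RegulatorPanel
from m6astrat.scoring import (gene_cluster_assign, m6a_score, regulator_network,
                              score_associations)
from tests.conftest import make_expr


def _signature_expr(n_genes=10, n_samples=50, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n_samples)
    load = rng.choice([-1.0, 1.0], size=n_genes)
    X = load[:, None] * z[None, :] + 0.5 * rng.normal(size=(n_genes, n_samples))
    return make_expr(X), z


def test_rank_one_data_has_zero_pc2():
    rng = np.random.default_rng(1)
    base = rng.normal(size=20)
    X = np.outer([1.0, 2.0, -1.5, 0.5], base)
    st = m6a_score(make_expr(X), [f"g{i}" for i in range(4)])
    assert np.allclose(st.table["pc2"], 0.0)
    assert np.allclose(st.table["m6a_score"], st.table["pc1"])


def test_score_invariant_to_gene_order():
    expr, _ = _signature_expr()
    genes = expr.gene_ids
    a = m6a_score(expr, genes)
    b = m6a_score(expr, list(reversed(genes)))
    assert np.allclose(a.table["m6a_score"], b.table["m6a_score"])


def test_projections_match_eigendecomposition_oracle():
    """PC projections agree with an independent eigendecomposition of the
    sample covariance of the z-scored signature."""
    expr, _ = _signature_expr(n_genes=8, n_samples=50, seed=3)
    st = m6a_score(expr, expr.gene_ids)
    V = expr.values.to_numpy()
    Z = (V - V.mean(axis=1, keepdims=True)) / V.std(axis=1, ddof=1, keepdims=True)
    C = np.cov(Z, rowvar=True, ddof=1)  # gene covariance; same eigvecs as sample SVD
    w, vecs = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    for c, col in enumerate(["pc1", "pc2"]):
        v = vecs[:, order[c]]
        proj = Z.T @ v
        # orientation rule: non-negative correlation with mean signature
        if np.dot(proj, Z.mean(axis=0)) < 0:
            proj = -proj
        assert np.allclose(np.abs(proj), np.abs(st.table[col]), atol=1e-8)
        assert np.allclose(proj, st.table[col], atol=1e-8)


def test_score_is_pc1_plus_pc2_and_groups_match_threshold():
    expr, _ = _signature_expr(seed=4)
    st = m6a_score(expr, expr.gene_ids)
    assert np.allclose(st.table["m6a_score"], st.table["pc1"] + st.table["pc2"])
    high = st.table["m6a_score"] > st.threshold
    assert (st.table.loc[high, "group"] == "high").all()
    assert (st.table.loc[~high, "group"] == "low").all()


def test_zero_variance_gene_dropped():
    expr, _ = _signature_expr(seed=5)
    vals = expr.values.copy()
    vals.iloc[0] = 3.0
    st = m6a_score(make_expr(vals.to_numpy()), [f"g{i}" for i in range(10)])
    assert "g0" not in st.genes_used


def test_too_few_genes_errors():
    expr, _ = _signature_expr()
    with pytest.raises(ValueError):
        m6a_score(expr, expr.gene_ids[:2])


def test_score_tracks_latent_factor():
    expr, z = _signature_expr(n_genes=20, n_samples=80, seed=6)
    st = m6a_score(expr, expr.gene_ids)
    r = abs(np.corrcoef(st.table["m6a_score"], z)[0, 1])
    assert r > 0.9


# ---------------------------------------------------------------- associations

def test_score_identical_to_tmb_ranking_gives_rho_one():
    expr, _ = _signature_expr(seed=7)
    st = m6a_score(expr, expr.gene_ids)
    tmb = pd.Series(pd.Series(st.table["m6a_score"]).rank().astype(int).to_numpy(),
                    index=st.table.index)
    out = score_associations(st, tmb=tmb)
    row = out[out["feature"] == "tmb"].iloc[0]
    assert row["statistic"] == pytest.approx(1.0)


def test_constant_marker_gives_p_one():
    expr, _ = _signature_expr(seed=8)
    st = m6a_score(expr, expr.gene_ids)
    marker = pd.DataFrame(np.ones((1, len(st.table))), index=["CD274"],
                          columns=st.table.index)
    out = score_associations(st, marker_expr=marker)
    assert out.iloc[0]["p"] == 1.0


def test_too_few_paired_observations_error():
    expr, _ = _signature_expr(seed=9)
    st = m6a_score(expr, expr.gene_ids)
    tmb = pd.Series([1, 2], index=st.table.index[:2])
    with pytest.raises(ValueError):
        score_associations(st, tmb=tmb)


def test_synthetic_tmb_association_recovered(default_cohort):
    co = default_cohort
    tg = co.truth_genes.set_index("gene")
    prognostic = sorted(tg.index[tg["prognostic"]])
    st = m6a_score(co.expression, prognostic)
    tmb = co.truth_samples.set_index("sample_id")["tmb"]
    out = score_associations(st, tmb=tmb)
    rho = out[out["feature"] == "tmb"]["statistic"].iloc[0]
    assert 0.25 <= abs(rho) <= 0.45


# ---------------------------------------------------------------- network

def test_regulator_network_structure(small_cohort):
    co = small_cohort
    net = regulator_network(co.expression, co.clinical, co.config.panel)
    nodes, edges = net["nodes"], net["edges"]
    assert set(nodes["gene"]) == set(co.config.panel.genes)
    assert set(nodes["direction"]) <= {"risk", "favorable", "na"}
    p = len(co.config.panel.genes)
    assert len(edges) <= p * (p - 1) // 2
    if len(edges):
        assert (edges["gene_a"] != edges["gene_b"]).all()
        recorded = set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy()))
        assert all((b, a) not in recorded for a, b in recorded)
        assert (edges["rho"].abs() <= 1).all()


def test_simulated_risk_gene_labeled_risk(default_cohort):
    """A gene with a planted positive log-hazard loading gets direction
    'risk'; a negative one gets 'favorable'."""
    co = default_cohort
    tg = co.truth_genes.set_index("gene")
    pos = tg[(tg["true_beta"] > 0) & tg["prognostic"]].index[0]
    neg = tg[(tg["true_beta"] < 0) & tg["prognostic"]].index[0]
    panel = RegulatorPanel({pos: "reader", neg: "writer"})
    net = regulator_network(co.expression, co.clinical, panel)
    nodes = net["nodes"].set_index("gene")
    assert nodes.loc[pos, "direction"] == "risk"
    assert nodes.loc[neg, "direction"] == "favorable"


# ---------------------------------------------------------------- gene clusters

def test_gene_cluster_recovery_and_determinism():
    """A strongly planted 3-cluster structure in the prognostic genes is
    recovered by the patient gene-clustering."""
    from m6astrat.synthetic_cohort import SimulationConfig, simulate_cohort
    co = simulate_cohort(SimulationConfig(
        n_samples=150, n_background_genes=50, n_prognostic_genes=60,
        n_immune_genes=10, prognostic_cluster_sep=1.5, seed=21))
    tg = co.truth_genes.set_index("gene")
    prognostic = sorted(tg.index[tg["prognostic"]])
    labels_a, res = gene_cluster_assign(co.expression, prognostic, k=3,
                                        reps=60, seed=5)
    labels_b, _ = gene_cluster_assign(co.expression, prognostic, k=3,
                                      reps=60, seed=5)
    assert np.array_equal(labels_a, labels_b)
    from sklearn.metrics import adjusted_rand_score
    truth = co.truth_samples["cluster"].to_numpy()
    assert adjusted_rand_score(truth, labels_a) >= 0.9
    with pytest.raises(ValueError):
        gene_cluster_assign(co.expression, prognostic, k=1)
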