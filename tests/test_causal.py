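"""DAG machinery, overlap weights, balance diagnostics and effect
estimation."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from listendiv import causal as ca
from oracles import all_dags, d_separated_oracle


# ------------------------------------------------------------- DAG model


def test_dagmodel_validation():
    with pytest.raises(ValueError):
        ca.DAGModel.from_edges(["A -> B", "B -> A"], exposure="A", outcome="B")
    with pytest.raises(ValueError):
        ca.DAGModel.from_edges(["A -> B"], exposure="A", outcome="Z")


def test_dag_from_file(tmp_path):
    path = tmp_path / "model.dag"
    path.write_text("# comment\npopulation_size -> bid\nincome -> bid\n\n")
    dag = ca.DAGModel.from_file(path, exposure="population_size", outcome="bid")
    assert set(dag.graph.edges) == {("population_size", "bid"), ("income", "bid")}


def test_implied_independencies_chain_and_collider():
    chain = ca.DAGModel.from_edges(["A -> B", "B -> C"], exposure="A", outcome="C")
    claims = {str(c) for c in ca.implied_independencies(chain)}
    assert claims == {"A _||_ C | B"}
    collider = ca.DAGModel.from_edges(["A -> C", "B -> C"], exposure="A", outcome="C")
    claims = ca.implied_independencies(collider)
    assert len(claims) == 1 and claims[0].given == frozenset()
    # and the DAG does NOT imply A _||_ B | C
    assert not nx.is_d_separator(collider.graph, {"A"}, {"B"}, {"C"})


def test_implied_independencies_cyclic_raises():
    g = nx.DiGraph([("A", "B"), ("B", "A")])
    with pytest.raises(ValueError):
        ca.implied_independencies(g)


def test_implied_independencies_hold_by_dsep_on_random_dags(rng):
    """Every claim in the pairwise basis is an actual d-separation."""
    for _ in range(50):
        g = nx.gnp_random_graph(6, 0.4, seed=int(rng.integers(1 << 30)), directed=True)
        dag = nx.DiGraph((a, b) for a, b in g.edges if a < b)
        dag.add_nodes_from(range(6))
        for claim in ca.implied_independencies(dag):
            assert nx.is_d_separator(dag, {claim.x}, {claim.y}, set(claim.given))


def test_dsep_matches_bruteforce_on_small_dags(rng):
    """networkx d-separation agrees with exhaustive path enumeration on
    random 4-5-node DAGs and all conditioning sets (spot check; the full
    sweep lives in the acceptance suite)."""
    for _ in range(40):
        n = int(rng.integers(3, 6))
        nodes = list(range(n))
        edges = [
            (a, b)
            for a in nodes
            for b in nodes
            if a < b and rng.random() < 0.4
        ]
        g = nx.DiGraph(edges)
        g.add_nodes_from(nodes)
        for x, y in itertools.combinations(nodes, 2):
            others = [w for w in nodes if w not in (x, y)]
            for r in range(len(others) + 1):
                for z in itertools.combinations(others, r):
                    assert nx.is_d_separator(g, {x}, {y}, set(z)) == d_separated_oracle(
                        edges, x, y, z, nodes
                    )


# ------------------------------------------------------------- adjustment


def test_minimal_adjustment_confounder_triangle():
    dag = ca.DAGModel.from_edges(
        ["Z -> X", "Z -> Y", "X -> Y"], exposure="X", outcome="Y"
    )
    assert ca.minimal_adjustment_sets(dag) == [frozenset({"Z"})]
    assert ca.minimal_adjustment_sets(dag, effect="total") == [frozenset({"Z"})]


def test_minimal_adjustment_m_bias_empty_set():
    dag = ca.DAGModel.from_edges(
        ["U1 -> X", "U1 -> C", "U2 -> C", "U2 -> Y", "X -> Y"],
        exposure="X",
        outcome="Y",
    )
    assert ca.minimal_adjustment_sets(dag) == [frozenset()]


def test_minimal_adjustment_mediator_for_direct_effect():
    dag = ca.DAGModel.from_edges(
        ["X -> M", "M -> Y", "X -> Y"], exposure="X", outcome="Y"
    )
    assert ca.minimal_adjustment_sets(dag, effect="direct") == [frozenset({"M"})]
    # the total effect needs no adjustment: no backdoor path exists
    assert ca.minimal_adjustment_sets(dag, effect="total") == [frozenset()]


def test_default_dag_adjustment_set_is_full_covariate_set():
    for outcome in ("bid", "wid"):
        dag = ca.default_dag(outcome)
        sets = ca.minimal_adjustment_sets(dag)
        assert len(sets) == 1
        assert sets[0] == frozenset(
            {
                "age",
                "gender",
                "income",
                "education",
                "immigration",
                "venues",
                "social_connections",
                "algorithmic_share",
            }
        )


def test_minimal_sets_are_valid_and_minimal(rng):
    """No returned set has a valid proper subset; each is valid."""
    dag = ca.default_dag("wid")
    g = dag.graph
    for z in ca.minimal_adjustment_sets(dag):
        assert ca._is_valid_direct_adjustment(g, dag.exposure, dag.outcome, z)
        for drop in z:
            assert not ca._is_valid_direct_adjustment(
                g, dag.exposure, dag.outcome, z - {drop}
            )


# ------------------------------------------------------------- independence tests


def _simulate_chain(n, rng, violate=False):
    a = rng.standard_normal(n)
    b = 0.8 * a + rng.standard_normal(n)
    c = 0.8 * b + rng.standard_normal(n)
    if violate:
        c = c + 0.8 * a  # direct A -> C edge the DAG does not declare
    return pd.DataFrame({"A": a, "B": b, "C": c})


def test_independence_tests_consistent_data(rng):
    dag = ca.DAGModel.from_edges(["A -> B", "B -> C"], exposure="A", outcome="C")
    claims = ca.implied_independencies(dag)
    report = ca.test_independencies(claims, _simulate_chain(2000, rng))
    assert not report["rejected"].any()


def test_independence_tests_flag_violated_edge(rng):
    dag = ca.DAGModel.from_edges(["A -> B", "B -> C"], exposure="A", outcome="C")
    claims = ca.implied_independencies(dag)
    report = ca.test_independencies(claims, _simulate_chain(2000, rng, violate=True))
    assert report["rejected"].all()


def test_independence_tests_empty_claims():
    report = ca.test_independencies([], pd.DataFrame({"A": [1.0, 2.0]}))
    assert report.empty


def test_partial_correlation_removes_common_cause(rng):
    z = rng.standard_normal(3000)
    x = z + 0.5 * rng.standard_normal(3000)
    y = z + 0.5 * rng.standard_normal(3000)
    data = pd.DataFrame({"x": x, "y": y, "z": z})
    r_marg, p_marg = ca.partial_correlation(data, "x", "y")
    r_cond, p_cond = ca.partial_correlation(data, "x", "y", ["z"])
    assert r_marg > 0.5 and p_marg < 1e-6
    assert abs(r_cond) < 0.05 and p_cond > 0.01


# ------------------------------------------------------------- ATO weights


def test_ato_weights_covariate_free_groups(rng):
    t = np.repeat(["small", "large"], 200)
    cov = pd.DataFrame({"x": np.zeros(400)})
    pw = ca.ato_weights(cov, t, poly_degree=1)
    np.testing.assert_allclose(pw.weights, 1.0, atol=1e-6)


def test_ato_weights_binary_reduction(rng):
    x = rng.standard_normal(3000)
    t = np.where(rng.random(3000) < 1 / (1 + np.exp(-x)), "large", "small")
    pw = ca.ato_weights(pd.DataFrame({"x": x}), t, poly_degree=1)
    e_large = pw.propensities["large"].to_numpy()
    manual = np.where(t == "large", 1 - e_large, e_large)
    for lv in ("small", "large"):
        m = t == lv
        manual[m] /= manual[m].mean()
    np.testing.assert_allclose(pw.weights, manual, atol=1e-10)


def test_ato_weights_balance_confounded_groups(rng):
    n = 6000
    x = rng.standard_normal(n)
    logits = np.column_stack([0.8 * x, np.zeros(n), -0.8 * x])
    p = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
    t = np.array(["small", "medium", "large"])[
        (p.cumsum(1) < rng.random((n, 1))).sum(1)
    ]
    cov = pd.DataFrame({"x": x})
    pw = ca.ato_weights(cov, t)
    bal = ca.smd_balance(cov, t, pw.weights)
    assert bal["smd_unweighted"].abs().max() > 0.3
    assert bal["smd_weighted"].abs().max() < 0.05
    assert (bal["smd_weighted"].abs() < bal["smd_unweighted"].abs()).all()


def test_ato_weights_affine_invariance(rng):
    x = rng.standard_normal(800)
    t = np.where(x + 0.5 * rng.standard_normal(800) > 0, "large", "small")
    w1 = ca.ato_weights(pd.DataFrame({"x": x}), t).weights
    w2 = ca.ato_weights(pd.DataFrame({"x": 100.0 * x - 7.0}), t).weights
    np.testing.assert_allclose(w1, w2, atol=1e-6)


def test_ato_weights_validation(rng):
    with pytest.raises(ValueError):
        ca.ato_weights(pd.DataFrame({"x": [np.nan, 1.0]}), np.array(["a", "b"]))
    with pytest.raises(ValueError):
        ca.ato_weights(pd.DataFrame({"x": [1.0, 2.0]}), np.array(["a", "a"]))


# ------------------------------------------------------------- SMD


def test_smd_hand_values(rng):
    a = rng.normal(0, 1, 20000)
    b = rng.normal(1, 1, 20000)
    cov = pd.DataFrame({"v": np.r_[a, b]})
    t = np.repeat(["small", "large"], 20000)
    bal = ca.smd_balance(cov, t)
    assert bal["smd_unweighted"].iloc[0] == pytest.approx(-1.0, abs=0.05)
    same = ca.smd_balance(pd.DataFrame({"v": np.r_[a, a]}), t)
    assert same["smd_unweighted"].iloc[0] == pytest.approx(0.0, abs=1e-12)


# ------------------------------------------------------------- effects


def _three_group_sim(rng, n=6000, confound=0.0, direct=0.0):
    x = rng.standard_normal(n)
    logits = np.column_stack([confound * x, np.zeros(n), -confound * x])
    p = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
    t = np.array(["small", "medium", "large"])[
        (p.cumsum(1) < rng.random((n, 1))).sum(1)
    ]
    g_ix = pd.Index(["small", "medium", "large"]).get_indexer(t)
    y = direct * g_ix + confound * x + rng.standard_normal(n)
    return pd.DataFrame({"x": x, "y": y, "t": t})


def test_weighted_effect_null_simulation(rng):
    df = _three_group_sim(rng)
    pw = ca.ato_weights(df[["x"]], df["t"].to_numpy())
    effs = ca.weighted_effect(df["y"], df["t"].to_numpy(), pw.weights)
    # ~3 standard errors of a mean contrast at this sample size
    for e in effs:
        assert abs(e.adjusted) < 0.1
        assert abs(e.unadjusted) < 0.1


def test_weighted_effect_pure_confounding(rng):
    df = _three_group_sim(rng, confound=1.0)
    pw = ca.ato_weights(df[["x"]], df["t"].to_numpy())
    effs = {e.contrast: e for e in ca.weighted_effect(df["y"], df["t"].to_numpy(), pw.weights)}
    assert effs["large-small"].unadjusted < -0.5  # bias from the confounder
    assert abs(effs["large-small"].adjusted) < 0.08


def test_weighted_effect_recovers_injected_direct_effect(rng):
    delta = 0.8
    df = _three_group_sim(rng, confound=0.8, direct=delta)
    pw = ca.ato_weights(df[["x"]], df["t"].to_numpy())
    effs = {
        e.contrast: e
        for e in ca.weighted_effect(
            df["y"], df["t"].to_numpy(), pw.weights, standardise=False
        )
    }
    assert effs["medium-small"].adjusted == pytest.approx(delta, rel=0.1)
    assert effs["large-small"].adjusted == pytest.approx(2 * delta, rel=0.1)


def test_weighted_effect_small_group_raises(rng):
    y = np.arange(5.0)
    t = np.array(["small", "small", "medium", "medium", "large"])
    with pytest.raises(ValueError):
        ca.weighted_effect(y, t, np.ones(5))


def test_effect_estimate_ci_invariant():
    with pytest.raises(ValueError):
        ca.EffectEstimate(
            contrast="medium-small",
            adjusted=1.0,
            unadjusted=0.5,
            adjusted_ci=(2.0, 3.0),
        )


# ------------------------------------------------------------- bootstrap


def test_bootstrap_causal_seed_reproducible(rng):
    df = _three_group_sim(rng, n=900, confound=0.6)
    a = ca.bootstrap_causal(df, ["x"], "y", "t", n_reps=30, seed=5)
    b = ca.bootstrap_causal(df, ["x"], "y", "t", n_reps=30, seed=5)
    pd.testing.assert_frame_equal(a, b)
    assert (a["adjusted_ci_low"] <= a["adjusted"]).all()
    assert (a["adjusted"] <= a["adjusted_ci_high"]).all()


def test_bootstrap_causal_ci_shrinks_with_n(rng):
    widths = []
    for n in (400, 1600, 6400):
        df = _three_group_sim(rng, n=n, confound=0.5)
        res = ca.bootstrap_causal(df, ["x"], "y", "t", n_reps=60, seed=2)
        w = (res["adjusted_ci_high"] - res["adjusted_ci_low"]).mean()
        widths.append(w)
    assert widths[0] > widths[1] > widths[2]
    # roughly 1/sqrt(n): a factor-4 n step should halve the width
    assert 1.3 < widths[0] / widths[1] < 3.2
    assert 1.3 < widths[1] / widths[2] < 3.2


def test_bootstrap_causal_null_coverage(rng):
    """Percentile CIs cover the null truth at close to nominal rate."""
    hits = 0
    trials = 60
    for i in range(trials):
        df = _three_group_sim(rng, n=400, confound=0.5)
        res = ca.bootstrap_causal(
            df, ["x"], "y", "t", n_reps=60, seed=int(rng.integers(1 << 30))
        )
        row = res.set_index("contrast").loc["large-small"]
        hits += row["adjusted_ci_low"] <= 0.0 <= row["adjusted_ci_high"]
    assert hits / trials >= 0.85


def test_bootstrap_causal_cluster_resampling(rng):
    df = _three_group_sim(rng, n=900, confound=0.5)
    df["area"] = np.repeat(np.arange(30), 30)
    res = ca.bootstrap_causal(
        df, ["x"], "y", "t", n_reps=30, seed=1, cluster_col="area"
    )
    assert len(res) == 2
    assert (res["adjusted_ci_low"] <= res["adjusted_ci_high"]).all()
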