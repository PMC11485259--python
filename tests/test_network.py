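import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidscore import network as net
from lipidscore.lipids import LipidMatrix
from lipidscore.scoring import ScoreDefinition


def _random_dag(n_nodes, p_edge, seed):
    rng = np.random.default_rng(seed)
    dag = nx.DiGraph()
    dag.add_nodes_from(range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                dag.add_edge(i, j)
    return dag


class TestPartialCorrelationTest:
    def test_identical_columns(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        df = pd.DataFrame({"a": x, "b": x})
        r, p = net.partial_correlation_test(df, "a", "b")
        assert r > 0.999
        assert p < 1e-12

    def test_conditioning_set_too_large(self):
        df = pd.DataFrame(np.random.default_rng(2).standard_normal((6, 5)))
        with pytest.raises(ValueError, match="conditioning set"):
            net.partial_correlation_test(df, 0, 1, (2, 3, 4))

    def test_null_p_uniform(self):
        ps = []
        for rep in range(400):
            rng = np.random.default_rng(rep)
            df = pd.DataFrame({"a": rng.standard_normal(120),
                               "b": rng.standard_normal(120)})
            ps.append(net.partial_correlation_test(df, "a", "b")[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_conditioning_removes_chain_correlation(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(3000)
        b = 0.8 * a + 0.6 * rng.standard_normal(3000)
        c = 0.8 * b + 0.6 * rng.standard_normal(3000)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        r_marg, _ = net.partial_correlation_test(df, "a", "c")
        r_cond, p_cond = net.partial_correlation_test(df, "a", "c", ("b",))
        assert abs(r_cond) < abs(r_marg)
        assert p_cond > 0.001


class TestPcSkeleton:
    def test_chain_structure(self):
        rng = np.random.default_rng(4)
        n = 5000
        a = rng.standard_normal(n)
        b = 0.7 * a + 0.7 * rng.standard_normal(n)
        c = 0.7 * b + 0.7 * rng.standard_normal(n)
        ng = net.pc_skeleton(pd.DataFrame({"A": a, "B": b, "C": c}), alpha=0.01)
        assert set(map(frozenset, ng.graph.edges)) == {frozenset("AB"), frozenset("BC")}
        assert ng.sepsets[frozenset(("A", "C"))] == ("B",)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_d_separation_oracle_recovers_skeleton(self, seed):
        dag = _random_dag(10, 0.3, seed)
        oracle = net.d_separation_oracle(dag)
        dummy = pd.DataFrame(np.zeros((100, 10)), columns=range(10))
        ng = net.pc_skeleton(dummy, alpha=0.5, ci_test=oracle)
        assert set(map(frozenset, ng.graph.edges)) == set(map(frozenset, dag.edges))

    def test_column_order_invariance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((500, 6)),
                          columns=list("abcdef"))
        df["b"] += 0.8 * df["a"]
        df["c"] += 0.8 * df["b"]
        e1 = set(map(frozenset, net.pc_skeleton(df, alpha=0.05).graph.edges))
        e2 = set(map(frozenset,
                     net.pc_skeleton(df[list("fedcba")], alpha=0.05).graph.edges))
        assert e1 == e2

    def test_alpha_validated(self):
        df = pd.DataFrame(np.random.default_rng(6).standard_normal((50, 3)))
        with pytest.raises(ValueError):
            net.pc_skeleton(df, alpha=1.5)

    def test_n_le_p_warns(self):
        df = pd.DataFrame(np.random.default_rng(7).standard_normal((5, 6)))
        with pytest.warns(UserWarning, match="unstable"):
            net.pc_skeleton(df, alpha=0.01, max_cond=0)

    def test_removed_pairs_have_sepsets(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.standard_normal((800, 5)), columns=list("abcde"))
        ng = net.pc_skeleton(df, alpha=0.05)
        all_pairs = {frozenset((u, v)) for u in "abcde" for v in "abcde" if u < v}
        present = set(map(frozenset, ng.graph.edges))
        for pair in all_pairs - present:
            assert pair in ng.sepsets


class TestLouvain:
    def test_two_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        cl = net.louvain_clusters(g, seed=1)
        assert cl.members() == {0: [0, 1, 2, 3, 4], 1: [5, 6, 7, 8, 9]}

    def test_edgeless_singletons(self):
        g = nx.empty_graph(4)
        cl = net.louvain_clusters(g, seed=1)
        assert len(set(cl.labels.values())) == 4
        assert cl.modularity == 0.0

    def test_complete_graph_single_cluster(self):
        cl = net.louvain_clusters(nx.complete_graph(6), seed=1)
        assert len(set(cl.labels.values())) == 1

    def test_modularity_at_least_singletons(self):
        g = nx.gnp_random_graph(20, 0.2, seed=9)
        cl = net.louvain_clusters(g, seed=2)
        singleton = nx.community.modularity(g, [{n} for n in g.nodes])
        assert cl.modularity >= singleton

    def test_deterministic(self):
        g = nx.gnp_random_graph(30, 0.15, seed=10)
        a = net.louvain_clusters(g, seed=3)
        b = net.louvain_clusters(g, seed=3)
        assert a.labels == b.labels

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            net.louvain_clusters(nx.empty_graph(0), seed=1)

    def test_labels_contiguous(self):
        g = nx.gnp_random_graph(15, 0.2, seed=11)
        cl = net.louvain_clusters(g, seed=4)
        labels = sorted(set(cl.labels.values()))
        assert labels == list(range(len(labels)))


class TestClusterScores:
    @staticmethod
    def _setup(seed=12):
        rng = np.random.default_rng(seed)
        cols = ["CE.FA16:0", "CE.FA18:1", "DAG.FA16:0", "DAG.FA18:1"]
        m = LipidMatrix(pd.DataFrame(rng.standard_normal((25, 4)), columns=cols), "log")
        sdef = ScoreDefinition(tuple(cols), (-0.5, -0.3, -0.2, -0.1), scale=2.0)
        return m, sdef

    def test_additivity_conservation(self):
        from lipidscore.scoring import compute_score
        m, sdef = self._setup()
        cl = net.ClusterAssignment({"CE.FA16:0": 0, "CE.FA18:1": 0,
                                    "DAG.FA16:0": 1, "DAG.FA18:1": 1}, 0.3)
        cs = net.cluster_scores(m, sdef, cl)
        np.testing.assert_allclose(cs.sum(axis=1), compute_score(m, sdef), atol=1e-10)

    def test_single_cluster_equals_full(self):
        from lipidscore.scoring import compute_score
        m, sdef = self._setup()
        cl = net.ClusterAssignment({v: 0 for v in sdef.variables}, 0.0)
        cs = net.cluster_scores(m, sdef, cl)
        np.testing.assert_allclose(cs["cluster_0"], compute_score(m, sdef))

    def test_singleton_clusters(self):
        m, sdef = self._setup()
        cl = net.ClusterAssignment({v: i for i, v in enumerate(sdef.variables)}, 0.0)
        cs = net.cluster_scores(m, sdef, cl)
        for i, (v, w) in enumerate(zip(sdef.variables, sdef.weights)):
            np.testing.assert_allclose(cs[f"cluster_{i}"],
                                       m.values[v] * w / sdef.scale)

    def test_partition_enforced(self):
        m, sdef = self._setup()
        cl = net.ClusterAssignment({"CE.FA16:0": 0}, 0.0)
        with pytest.raises(ValueError, match="partition"):
            net.cluster_scores(m, sdef, cl)


def _linear_outcome_fitter(data: pd.DataFrame, outcome: str):
    """Fast OLS-based fitter for unit tests (the Cox fitter is exercised in
    the acceptance suite)."""
    from lipidscore._stats import ols

    def fit(node, adjust):
        cols = [node, *adjust]
        X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy() for c in cols])
        res = ols(data[outcome].to_numpy(), X, ("intercept", *cols))
        return float(res.p[1]), float(np.sign(res.beta[1]))

    return fit


class TestNetCoupler:
    @staticmethod
    def _chain_data(n=4000, seed=13):
        # X -> M -> Y: only M directly affects the outcome
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        m = 0.8 * x + 0.6 * rng.standard_normal(n)
        y = 0.7 * m + rng.standard_normal(n)
        data = pd.DataFrame({"X": x, "M": m, "Y": y})
        g = nx.Graph([("X", "M")])
        return data, g

    def test_chain_classification(self):
        data, g = self._chain_data()
        out = net.netcoupler_classify(g, _linear_outcome_fitter(data, "Y"),
                                      nodes=["X", "M"])
        assert out.loc["M", "status"] == "direct"
        assert out.loc["X", "status"] in ("none", "ambiguous")

    def test_null_outcome_all_none(self):
        rng = np.random.default_rng(16)
        data = pd.DataFrame(rng.standard_normal((800, 4)), columns=list("abcd"))
        data["y"] = rng.standard_normal(800)
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
        out = net.netcoupler_classify(g, _linear_outcome_fitter(data, "y"),
                                      nodes=list("abcd"))
        # the all-subsets conjunction protects against false "direct" calls
        assert (out["status"] == "direct").sum() == 0
        assert (out["status"] == "none").mean() >= 0.5

    def test_isolated_node_with_effect(self):
        rng = np.random.default_rng(15)
        data = pd.DataFrame({"a": rng.standard_normal(500)})
        data["y"] = 0.8 * data["a"] + rng.standard_normal(500)
        g = nx.Graph()
        g.add_node("a")
        out = net.netcoupler_classify(g, _linear_outcome_fitter(data, "y"), nodes=["a"])
        assert out.loc["a", "status"] == "direct"
        assert out.loc["a", "n_submodels"] == 1

    def test_degree_cap(self):
        g = nx.star_graph(6)  # center node 0 has degree 6
        data = pd.DataFrame(np.random.default_rng(16).standard_normal((50, 7)),
                            columns=range(7))
        data["y"] = 0.0 * data[0] + np.random.default_rng(17).standard_normal(50)
        out = net.netcoupler_classify(g, _linear_outcome_fitter(data, "y"),
                                      degree_cap=3)
        assert out.loc[0, "status"] == "unevaluated"

    def test_empty_graph_reduces_to_per_node_models(self):
        rng = np.random.default_rng(18)
        data = pd.DataFrame(rng.standard_normal((300, 3)), columns=list("abc"))
        data["y"] = 0.9 * data["a"] + rng.standard_normal(300)
        g = nx.empty_graph(0)
        g.add_nodes_from("abc")
        out = net.netcoupler_classify(g, _linear_outcome_fitter(data, "y"))
        assert (out["n_submodels"] == 1).all()
        assert out.loc["a", "status"] == "direct"


def test_write_graph(tmp_path):
    rng = np.random.default_rng(19)
    df = pd.DataFrame(rng.standard_normal((400, 4)), columns=list("abcd"))
    df["b"] += 0.9 * df["a"]
    ng = net.pc_skeleton(df, alpha=0.05)
    net.write_graph(ng, tmp_path / "edges.tsv", tmp_path / "g.graphml")
    edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
    assert {"source", "target"} <= set(edges.columns)
    back = nx.read_graphml(tmp_path / "g.graphml")
    assert back.number_of_edges() == ng.graph.number_of_edges()
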