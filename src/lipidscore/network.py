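"""Conditional-independence network, Louvain clusters and direct-effect screening.

The skeleton is learned with the order-independent ("stable") variant of the
PC algorithm: at each level the adjacency sets are frozen before edge tests,
so the output does not depend on variable ordering.  The default conditional
independence test is the Fisher z-transform of the sample partial
correlation.  Community detection uses Louvain modularity optimization on
the unweighted skeleton.  Direct-effect screening refits the outcome model
for every subset of a node's neighbors and classifies the node as a direct
effector only when the association is significant with a consistent sign
across all submodels.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class NetworkGraph:
    """Undirected skeleton with per-pair separation records."""

    graph: nx.Graph
    sepsets: dict = field(default_factory=dict)   # frozenset({i,j}) -> tuple of separators
    alpha: float | None = None

    @property
    def nodes(self):
        return list(self.graph.nodes)

    def edge_list(self) -> pd.DataFrame:
        rows = [(u, v, d.get("pcorr_marginal", np.nan), d.get("pcorr_min", np.nan))
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "pcorr_marginal", "pcorr_min"])


def partial_correlation_test(data, i, j, conditioning_set=()) -> tuple[float, float]:
    """Fisher-z test of the partial correlation of columns i, j given a set.

    Returns ``(partial correlation, two-sided p)``.  Requires
    ``len(S) <= n - 4`` and complete data.
    """
    df = pd.DataFrame(data)
    S = list(conditioning_set)
    n = len(df)
    if len(S) > n - 4:
        raise ValueError(f"conditioning set too large: |S|={len(S)} with n={n}")
    cols = [i, j, *S]
    sub = df[cols].to_numpy(dtype=float)
    if np.isnan(sub).any():
        raise ValueError("partial correlation requires complete data")
    corr = np.corrcoef(sub, rowvar=False)
    if not S:
        r = corr[0, 1]
    else:
        try:
            prec = np.linalg.inv(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular conditioning regression") from exc
        r = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    r = float(np.clip(r, -0.999999999, 0.999999999))
    z = np.arctanh(r) * np.sqrt(max(n - len(S) - 3, 1))
    p = float(2 * stats.norm.sf(abs(z)))
    return r, p


def pc_skeleton(data: pd.DataFrame, alpha: float = 0.01, *,
                max_cond: int | None = None, ci_test=None) -> NetworkGraph:
    """Order-independent PC skeleton over the columns of ``data``.

    ``ci_test(i, j, S) -> (stat, p)`` may be injected (e.g. a d-separation
    oracle); by default the Fisher-z partial correlation test on ``data``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    nodes = list(data.columns)
    n, p = data.shape
    if n <= p:
        warnings.warn(f"n={n} <= p={p}: skeleton estimates may be unstable")
    if ci_test is None:
        def ci_test(i, j, S):
            return partial_correlation_test(data, i, j, S)

    g = nx.complete_graph(nodes)
    sepsets: dict[frozenset, tuple] = {}
    for u, v in g.edges:
        r, _ = ci_test(u, v, ())
        g.edges[u, v]["pcorr_marginal"] = r
        g.edges[u, v]["pcorr_min"] = abs(r)
    level = 0
    while True:
        # freeze adjacencies at the start of the level: order independence
        adj = {v: set(g.neighbors(v)) for v in nodes}
        if all(len(adj[v]) - 1 < level for v in nodes):
            break
        if max_cond is not None and level > max_cond:
            break
        for u, v in sorted(g.edges):
            removed = False
            for side in (sorted(adj[u] - {v}), sorted(adj[v] - {u})):
                if len(side) < level or removed:
                    continue
                for S in itertools.combinations(side, level):
                    r, pval = ci_test(u, v, S)
                    if g.has_edge(u, v):
                        prev = g.edges[u, v].get("pcorr_min", np.inf)
                        g.edges[u, v]["pcorr_min"] = min(prev, abs(r))
                    if pval > alpha:
                        g.remove_edge(u, v)
                        sepsets[frozenset((u, v))] = tuple(S)
                        removed = True
                        break
        level += 1
    return NetworkGraph(graph=g, sepsets=sepsets, alpha=alpha)


def d_separation_oracle(dag: nx.DiGraph):
    """CI test backed by d-separation on a known DAG (p=1 if separated else 0)."""
    def test(i, j, S):
        sep = nx.is_d_separator(dag, {i}, {j}, set(S))
        return (0.0 if sep else 1.0), (1.0 if sep else 0.0)
    return test


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    labels: dict           # node -> contiguous integer cluster label
    modularity: float

    def members(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, []).append(node)
        return {k: sorted(v) for k, v in sorted(out.items())}


def louvain_clusters(g: NetworkGraph | nx.Graph, resolution: float = 1.0,
                     seed: int = 0) -> ClusterAssignment:
    """Louvain modularity communities on the (unweighted) skeleton.

    Deterministic for a fixed seed; labels are contiguous, ordered by the
    smallest member node.  An edgeless graph yields singletons with
    modularity 0.
    """
    graph = g.graph if isinstance(g, NetworkGraph) else g
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if graph.number_of_edges() == 0:
        labels = {node: i for i, node in enumerate(sorted(graph.nodes, key=str))}
        return ClusterAssignment(labels=labels, modularity=0.0)
    comms = nx.community.louvain_communities(graph, resolution=resolution, seed=seed)
    comms = sorted((sorted(c, key=str) for c in comms), key=lambda c: str(c[0]))
    labels = {node: i for i, comm in enumerate(comms) for node in comm}
    mod = float(nx.community.modularity(graph, comms, resolution=resolution))
    return ClusterAssignment(labels=labels, modularity=mod)


def cluster_scores(m, sdef, clusters: ClusterAssignment) -> pd.DataFrame:
    """Per-sample, per-cluster weighted sub-sums of the full score.

    Clusters must partition the score variables; the unscaled cluster scores
    sum exactly to the unscaled full score (conservation).
    """
    from .scoring import compute_score, subscore

    members = clusters.members()
    covered = sorted(v for mem in members.values() for v in mem)
    if covered != sorted(sdef.variables):
        raise ValueError("clusters must partition the score variables exactly")
    out = {}
    for lab, mem in members.items():
        out[f"cluster_{lab}"] = compute_score(m, subscore(sdef, mem, variant="cluster_score"))
    return pd.DataFrame(out, index=m.values.index)


# ---------------------------------------------------------------------------
# Direct-effect screening
# ---------------------------------------------------------------------------

@dataclass
class NodeClassification:
    node: str
    status: str                  # direct | ambiguous | none | unevaluated
    n_submodels: int
    p_max: float | None = None
    p_min: float | None = None
    sign_consistent: bool | None = None


def netcoupler_classify(g: NetworkGraph | nx.Graph, outcome_fit, *,
                        nodes=None, threshold: float = 0.05,
                        degree_cap: int = 12) -> pd.DataFrame:
    """Classify each node's outcome association as direct / ambiguous / none.

    ``outcome_fit(node, adjustment_vars) -> (p, sign)`` fits the outcome
    model with the node as exposure adjusted for the given neighbors (plus
    whatever base covariates it closes over).  A node is ``direct`` when
    every neighbor-subset submodel is significant with a consistent
    coefficient sign, ``none`` when no submodel is significant, and
    ``ambiguous`` otherwise.  Nodes with degree above ``degree_cap`` are
    flagged ``unevaluated`` (the submodel loop is exponential in degree).
    BH-adjusted significance flags across nodes are reported alongside.
    """
    from .effects import bh_fdr

    graph = g.graph if isinstance(g, NetworkGraph) else g
    nodes = list(nodes) if nodes is not None else list(graph.nodes)
    rows = []
    empty_p = {}
    for node in nodes:
        nbrs = sorted(graph.neighbors(node)) if node in graph else []
        if len(nbrs) > degree_cap:
            logger.warning("node %r degree %d exceeds cap %d; unevaluated",
                           node, len(nbrs), degree_cap)
            rows.append(NodeClassification(node, "unevaluated", 0))
            continue
        ps, signs = [], []
        for k in range(len(nbrs) + 1):
            for S in itertools.combinations(nbrs, k):
                p, sign = outcome_fit(node, list(S))
                ps.append(p)
                signs.append(np.sign(sign))
        empty_p[node] = ps[0]
        sig = [p < threshold for p in ps]
        consistent = len(set(s for s in signs if s != 0)) <= 1
        if all(sig) and consistent:
            status = "direct"
        elif not any(sig):
            status = "none"
        else:
            status = "ambiguous"
        rows.append(NodeClassification(node, status, len(ps),
                                       p_max=max(ps), p_min=min(ps),
                                       sign_consistent=consistent))
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("node")
    evaluated = out.index[out["status"] != "unevaluated"]
    if len(evaluated):
        q, _ = bh_fdr(out.loc[evaluated, "p_max"].to_numpy())
        out.loc[evaluated, "q_max_bh"] = q
    return out


def cox_outcome_fitter(table: pd.DataFrame, base_covariates=(), **cox_kwargs):
    """Build an ``outcome_fit`` closure over a case-cohort table with node columns."""
    from .assoc import fit_prentice_cox

    def fit(node, adjust):
        res = fit_prentice_cox(table, node, [*adjust, *base_covariates], **cox_kwargs)
        return res.p, np.sign(res.log_hr)

    return fit


def write_graph(ng: NetworkGraph, edge_tsv, graphml=None) -> None:
    ng.edge_list().to_csv(edge_tsv, sep="\t", index=False)
    if graphml is not None:
        nx.write_graphml(ng.graph, graphml)
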