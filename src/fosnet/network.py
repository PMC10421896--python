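"""Thresholded functional networks and whole-graph summary measures.

A functional network keeps every atlas region as a node and draws an
undirected edge for each significantly *positive* correlation at a
stated p threshold (two thresholds, 0.05 and 0.01, are used in tandem to
check which properties are threshold-stable).  Edges carry the
correlation r and its Fisher z as weights.  Significant negative
correlations are counted as a diagnostic but never become edges.

Shortest-path measures are unweighted (path length = minimum number of
edges); weights enter only measures defined as weighted (weighted
degree).  Efficiency scores unreachable pairs as zero; the average path
length is taken over reachable pairs only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from .connectivity import CorrelationResult

__all__ = [
    "FunctionalNetwork",
    "GraphSummary",
    "build_network",
    "build_networks",
    "graph_summary",
    "compare_summaries",
    "distance_matrix",
]


@dataclass
class FunctionalNetwork:
    """Undirected graph of significant positive correlations.

    ``graph`` contains every region as a node (isolates included); each
    edge has attributes ``weight`` (r) and ``z`` (atanh r).
    """

    condition: str
    p_threshold: float
    graph: nx.Graph
    n_negative_significant: int
    source: str = ""

    @property
    def regions(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def isolates(self) -> list[str]:
        return [n for n, d in self.graph.degree() if d == 0]

    def edge_weights(self, scheme: str = "r") -> dict[tuple[str, str], float]:
        attr = {"r": "weight", "fisher_z": "z"}[scheme]
        return {(u, v): d[attr] for u, v, d in self.graph.edges(data=True)}

    def to_edge_list(self) -> pd.DataFrame:
        rows = [(u, v, d["weight"], d["z"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["src", "dst", "r", "z"])

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edge_list(self, path: str | Path) -> None:
        self.to_edge_list().to_csv(path, index=False, float_format="%.10g")


def build_network(corr: CorrelationResult, p_threshold: float) -> FunctionalNetwork:
    """Edge iff r > 0 and p < threshold (strict); all regions kept as nodes."""
    if not (0.0 < p_threshold < 1.0):
        raise ValueError(f"p threshold must lie in (0, 1), got {p_threshold}")
    g = nx.Graph()
    g.add_nodes_from(corr.regions)
    rv, pv = corr.r.to_numpy(), corr.p.to_numpy()
    codes = corr.regions
    n_neg = 0
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            r, p = rv[i, j], pv[i, j]
            if not (np.isfinite(r) and np.isfinite(p)):
                continue
            if p < p_threshold:
                if r > 0:
                    z = float(np.arctanh(min(r, 1 - 1e-15)))
                    g.add_edge(codes[i], codes[j], weight=float(r), z=z)
                elif r < 0:
                    n_neg += 1
    return FunctionalNetwork(
        condition=corr.condition,
        p_threshold=p_threshold,
        graph=g,
        n_negative_significant=n_neg,
        source=f"corr:{corr.condition}",
    )


def build_networks(corr: CorrelationResult, p_thresholds=(0.05, 0.01)) -> dict[float, FunctionalNetwork]:
    return {th: build_network(corr, th) for th in p_thresholds}


def distance_matrix(net: FunctionalNetwork) -> tuple[np.ndarray, list[str]]:
    """Unweighted all-pairs shortest-path distances (inf when unreachable)."""
    nodes = net.regions
    adj = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, weight=None, format="csr")
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    return dist, nodes


@dataclass
class GraphSummary:
    """Scalar and per-node descriptors of one functional network."""

    condition: str
    p_threshold: float
    n_nodes: int
    n_connected_nodes: int
    n_edges: int
    density: float       # over connected nodes
    density_all: float   # over all nodes
    average_degree: float
    average_weighted_degree: float
    average_clustering: float
    global_efficiency: float
    average_path_length: float
    max_eccentricity: float
    n_negative_significant: int
    nodal_efficiency: pd.Series
    degree: pd.Series
    weighted_degree: pd.Series
    clustering: pd.Series

    def scalars(self) -> dict:
        d = {
            k: v
            for k, v in asdict(self).items()
            if not isinstance(v, pd.Series)
        }
        return d

    def node_vector(self, measure: str) -> pd.Series:
        vectors = {
            "degree": self.degree,
            "weighted_degree": self.weighted_degree,
            "clustering": self.clustering,
            "nodal_efficiency": self.nodal_efficiency,
        }
        if measure not in vectors:
            raise KeyError(f"{measure!r} has no node-level vector")
        return vectors[measure]


def graph_summary(net: FunctionalNetwork) -> GraphSummary:
    """Density, degree, clustering, efficiency and path-length measures.

    Density is reported both over the connected nodes (the convention
    that matches a published 46-connected-node example) and over all
    nodes.  Maximum eccentricity is the largest finite shortest-path
    distance — "regions connected up to k edges".
    """
    g = net.graph
    nodes = net.regions
    n = len(nodes)
    m = g.number_of_edges()
    degree = pd.Series(dict(g.degree()), name="degree").reindex(nodes).astype(float)
    wdeg = pd.Series(dict(g.degree(weight="weight")), name="weighted_degree").reindex(nodes).astype(float)
    n_conn = int((degree > 0).sum())
    density = m / (n_conn * (n_conn - 1) / 2) if n_conn > 1 else 0.0
    density_all = m / (n * (n - 1) / 2) if n > 1 else 0.0
    clustering = pd.Series(nx.clustering(g), name="clustering").reindex(nodes).astype(float)

    dist, _ = distance_matrix(net)
    finite = np.isfinite(dist)
    np.fill_diagonal(finite, False)
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(dist == 0, np.inf, dist), 0.0)
    nodal_eff = pd.Series(inv.sum(axis=1) / (n - 1), index=nodes, name="nodal_efficiency") if n > 1 else pd.Series(dtype=float)
    global_eff = float(nodal_eff.mean()) if n > 1 else 0.0
    reachable = dist[finite]
    apl = float(reachable.mean()) if reachable.size else float("nan")
    max_ecc = float(reachable.max()) if reachable.size else 0.0

    return GraphSummary(
        condition=net.condition,
        p_threshold=net.p_threshold,
        n_nodes=n,
        n_connected_nodes=n_conn,
        n_edges=m,
        density=float(density),
        density_all=float(density_all),
        average_degree=float(degree.mean()) if n else 0.0,
        average_weighted_degree=float(wdeg.mean()) if n else 0.0,
        average_clustering=float(clustering.mean()) if n else 0.0,
        global_efficiency=global_eff,
        average_path_length=apl,
        max_eccentricity=max_ecc,
        n_negative_significant=net.n_negative_significant,
        nodal_efficiency=nodal_eff,
        degree=degree,
        weighted_degree=wdeg,
        clustering=clustering,
    )


@dataclass(frozen=True)
class SummaryComparison:
    measure: str
    scalar_a: float
    scalar_b: float
    difference: float
    welch_t: float | None = None
    welch_p: float | None = None
    ks_d: float | None = None
    ks_p: float | None = None


def compare_summaries(
    summary_a: GraphSummary,
    summary_b: GraphSummary,
    measure: str,
    method: str = "ks",
) -> SummaryComparison:
    """Compare one measure between two networks.

    Node-level measures support a Welch test on means
    (``node_level_welch``), a two-sample Kolmogorov-Smirnov test on the
    distributions (``ks``), or ``both``.  Scalar-only measures (e.g.
    density) yield only the scalar difference.
    """
    if method not in ("node_level_welch", "ks", "both"):
        raise ValueError(f"unknown method {method!r}")
    try:
        va, vb = summary_a.node_vector(measure), summary_b.node_vector(measure)
    except KeyError:
        sa = summary_a.scalars().get(measure)
        sb = summary_b.scalars().get(measure)
        if sa is None or sb is None:
            raise KeyError(f"unknown measure {measure!r}") from None
        return SummaryComparison(measure, float(sa), float(sb), float(sa - sb))

    sa, sb = float(va.mean()), float(vb.mean())
    welch_t = welch_p = ks_d = ks_p = None
    if method in ("node_level_welch", "both"):
        t, p = stats.ttest_ind(va.to_numpy(), vb.to_numpy(), equal_var=False)
        welch_t, welch_p = float(t), float(p)
    if method in ("ks", "both"):
        res = stats.ks_2samp(va.to_numpy(), vb.to_numpy())
        ks_d, ks_p = float(res.statistic), float(res.pvalue)
    return SummaryComparison(measure, sa, sb, sa - sb, welch_t, welch_p, ks_d, ks_p)
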