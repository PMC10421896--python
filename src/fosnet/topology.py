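"""Mesoscale structure and node importance of functional networks.

Community detection maximizes modularity (multilevel Louvain by default,
seed-fixed; leading-eigenvector and, for small graphs, exhaustive
enumeration are alternatives).  Each node's community role is scored by
the within-community degree z-score (WC) and the participation
coefficient (PC): provincial hubs concentrate their edges inside their
community (WC >= 1.5 and PC <= 0.3), connector hubs spread them across
communities (PC >= 0.8 and WC <= 1.5).

Two PC conventions circulate.  The Guimera-Amaral form
``1 - sum_s (k_is / k_i)^2`` (default) sums squared per-community edge
shares; the simple-ratio form ``1 - k_own / k_i`` uses only the node's
own community.  Both are provided.

Centrality-based hubs use four measures — weighted degree (Wdg, sum of
edge weights), eigenvector (Evc, principal eigenvector of the weighted
adjacency, per connected component, scaled to max 1), betweenness (Bet,
unnormalized, unweighted shortest paths) and closeness (Clo, over
reachable nodes) — and flag nodes in the top quartile of at least three
of them.  Hubs present at both p thresholds are "stable hubs".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .data_model import RegionAtlas
from .network import FunctionalNetwork, distance_matrix

__all__ = [
    "Partition",
    "detect_communities",
    "exhaustive_modularity_partition",
    "wc_zscore",
    "participation_coefficient",
    "classify_roles",
    "MesoscaleProfile",
    "CentralityTable",
    "centralities",
    "identify_hubs",
    "HubResult",
    "stable_hubs",
]

MEASURES = ("wdg", "evc", "bet", "clo")


@dataclass
class Partition:
    """A node -> community assignment with its modularity Q."""

    membership: dict[str, int]
    q: float
    algorithm: str
    seed: int | None
    weight_scheme: str

    @property
    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, c in self.membership.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]

    def composition(self, atlas: RegionAtlas) -> pd.DataFrame:
        """Community x anatomical-group membership counts."""
        gmap = atlas.group_map()
        rows = []
        for cid, members in enumerate(self.communities):
            counts: dict[str, int] = {}
            for node in members:
                counts[gmap.get(node, "?")] = counts.get(gmap.get(node, "?"), 0) + 1
            rows.append({"community": cid, "size": len(members), **counts})
        return pd.DataFrame(rows).fillna(0)


def _weight_attr(scheme: str) -> str | None:
    return {"r": "weight", "fisher_z": "z", "unweighted": None}[scheme]


def detect_communities(
    net: FunctionalNetwork,
    algorithm: str = "multilevel_louvain",
    weight_scheme: str = "fisher_z",
    seed: int = 0,
    n_restarts: int = 8,
) -> Partition:
    """Modularity-maximizing partition of the network.

    ``multilevel_louvain`` runs several seeded restarts and keeps the
    best-Q partition; ``leading_eigenvector`` uses the spectral
    heuristic; ``exhaustive_small`` enumerates every partition (<= 10
    non-isolated nodes) as an oracle.  An edgeless graph yields each
    node its own community with Q = 0.
    """
    g = net.graph
    attr = _weight_attr(weight_scheme)
    if g.number_of_edges() == 0:
        return Partition({n: i for i, n in enumerate(g.nodes)}, 0.0, algorithm, seed, weight_scheme)

    if algorithm == "multilevel_louvain":
        best, best_q = None, -math.inf
        for t in range(n_restarts):
            comms = nx.community.louvain_communities(g, weight=attr, seed=seed + t)
            q = nx.community.modularity(g, comms, weight=attr)
            if q > best_q + 1e-12:
                best, best_q = comms, q
        membership = {n: i for i, c in enumerate(best) for n in c}
        membership, best_q = _refine_single_moves(g, membership, attr)
        return Partition(membership, float(best_q), algorithm, seed, weight_scheme)

    if algorithm == "leading_eigenvector":
        nodes = list(g.nodes)
        index = {n: i for i, n in enumerate(nodes)}
        edges = [(index[u], index[v]) for u, v in g.edges]
        weights = [g[u][v][attr] for u, v in g.edges] if attr else None
        igg = ig.Graph(n=len(nodes), edges=edges)
        cl = igg.community_leading_eigenvector(weights=weights)
        membership = {nodes[i]: cl.membership[i] for i in range(len(nodes))}
        comms = {}
        for n, c in membership.items():
            comms.setdefault(c, set()).add(n)
        q = nx.community.modularity(g, comms.values(), weight=attr)
        return Partition(membership, float(q), algorithm, seed, weight_scheme)

    if algorithm == "exhaustive_small":
        return exhaustive_modularity_partition(net, weight_scheme)

    raise ValueError(f"unknown community algorithm {algorithm!r}")


def _refine_single_moves(g: nx.Graph, membership: dict, attr: str | None) -> tuple[dict, float]:
    """Deterministic local-moving refinement: relocate single nodes to the
    neighbouring (or a fresh) community while modularity improves.

    Escapes the coarse-grained local optima the multilevel heuristic can
    leave behind on small graphs; on large graphs it typically makes no
    move."""
    nodes = sorted(g.nodes, key=str)
    membership = dict(membership)

    def q_of(mem: dict) -> float:
        comms: dict[int, set] = {}
        for n, c in mem.items():
            comms.setdefault(c, set()).add(n)
        return nx.community.modularity(g, comms.values(), weight=attr)

    best_q = q_of(membership)
    improved = True
    while improved:
        improved = False
        for node in nodes:
            current = membership[node]
            candidates = {membership[nb] for nb in g.neighbors(node)} - {current}
            candidates.add(max(membership.values()) + 1)  # fresh singleton
            for cand in sorted(candidates):
                trial = dict(membership)
                trial[node] = cand
                q = q_of(trial)
                if q > best_q + 1e-12:
                    membership, best_q = trial, q
                    improved = True
    # renumber communities densely in first-appearance order
    remap: dict[int, int] = {}
    for n in nodes:
        remap.setdefault(membership[n], len(remap))
    return {n: remap[membership[n]] for n in membership}, best_q


def _memberships(n: int):
    """All set partitions of range(n) as restricted-growth strings."""
    def rec(i: int, a: list[int], mx: int):
        if i == n:
            yield tuple(a)
            return
        for c in range(mx + 2):
            a.append(c)
            yield from rec(i + 1, a, max(mx, c))
            a.pop()
    if n == 0:
        yield ()
    else:
        yield from rec(1, [0], 0)


def exhaustive_modularity_partition(net: FunctionalNetwork, weight_scheme: str = "fisher_z") -> Partition:
    """Globally optimal modularity partition by enumerating all partitions.

    Isolated nodes are split off first (each its own community, which
    never lowers Q); the connected remainder must have <= 10 nodes.
    """
    g = net.graph
    attr = _weight_attr(weight_scheme)
    active = [n for n, d in g.degree() if d > 0]
    if len(active) > 10:
        raise ValueError("exhaustive enumeration limited to 10 non-isolated nodes")
    k = len(active)
    A = nx.to_numpy_array(g, nodelist=active, weight=attr)
    deg = A.sum(axis=1)
    two_m = A.sum()
    B = A - np.outer(deg, deg) / two_m
    best_q, best_a = -math.inf, None
    for a in _memberships(k):
        arr = np.asarray(a)
        same = arr[:, None] == arr[None, :]
        q = float((B * same).sum() / two_m)
        if q > best_q + 1e-12:
            best_q, best_a = q, arr
    membership = {n: int(best_a[i]) for i, n in enumerate(active)}
    next_c = int(best_a.max()) + 1 if k else 0
    for n in g.nodes:
        if n not in membership:
            membership[n] = next_c
            next_c += 1
    return Partition(membership, best_q if k else 0.0, "exhaustive_small", None, weight_scheme)


def _check_cover(net: FunctionalNetwork, partition: Partition) -> None:
    missing = set(net.graph.nodes) - set(partition.membership)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)}")


def wc_zscore(net: FunctionalNetwork, partition: Partition) -> pd.Series:
    """Within-community degree z-score (population SD; SD = 0 -> z = 0).

    z_i = (kappa_i - mean_c) / sd_c with kappa_i the node's number of
    edges to its own community and the moments taken over that
    community's nodes.
    """
    _check_cover(net, partition)
    g = net.graph
    mem = partition.membership
    kappa = {
        n: sum(1 for nb in g.neighbors(n) if mem[nb] == mem[n]) for n in g.nodes
    }
    z = {}
    for comm in partition.communities:
        ks = np.array([kappa[n] for n in comm], dtype=float)
        mu, sd = ks.mean(), ks.std()  # population convention
        for n in comm:
            z[n] = 0.0 if sd == 0 else (kappa[n] - mu) / sd
    return pd.Series(z, name="wc_zscore").reindex(list(g.nodes))


def participation_coefficient(
    net: FunctionalNetwork, partition: Partition, variant: str = "guimera"
) -> pd.Series:
    """Participation coefficient per node (isolated nodes score 0)."""
    if variant not in ("guimera", "simple_ratio"):
        raise ValueError(f"unknown variant {variant!r}")
    _check_cover(net, partition)
    g = net.graph
    mem = partition.membership
    pc = {}
    for n in g.nodes:
        k = g.degree(n)
        if k == 0:
            pc[n] = 0.0
            continue
        shares: dict[int, int] = {}
        for nb in g.neighbors(n):
            shares[mem[nb]] = shares.get(mem[nb], 0) + 1
        if variant == "guimera":
            pc[n] = 1.0 - sum((c / k) ** 2 for c in shares.values())
        else:
            pc[n] = 1.0 - shares.get(mem[n], 0) / k
    return pd.Series(pc, name="participation").reindex(list(g.nodes))


@dataclass
class MesoscaleProfile:
    """WC z-score, PC and the provincial/connector role per node."""

    table: pd.DataFrame  # columns wc_zscore, participation, role
    wc_threshold: float
    pc_provincial: float
    pc_connector: float

    def roles(self, role: str) -> list[str]:
        return self.table.index[self.table["role"] == role].tolist()


def classify_roles(
    wc: pd.Series,
    pc: pd.Series,
    wc_threshold: float = 1.5,
    pc_provincial: float = 0.3,
    pc_connector: float = 0.8,
) -> MesoscaleProfile:
    """Provincial iff WC >= 1.5 and PC <= 0.3; connector iff PC >= 0.8 and
    WC <= 1.5; otherwise neither.  The two rules are exclusive by
    construction of the thresholds."""
    table = pd.DataFrame({"wc_zscore": wc, "participation": pc})
    provincial = (table["wc_zscore"] >= wc_threshold) & (table["participation"] <= pc_provincial)
    connector = (table["participation"] >= pc_connector) & (table["wc_zscore"] <= wc_threshold)
    role = np.where(provincial, "provincial", np.where(connector, "connector", "neither"))
    table["role"] = role
    return MesoscaleProfile(table, wc_threshold, pc_provincial, pc_connector)


@dataclass
class CentralityTable:
    """Four centrality measures with descending ranks per node."""

    table: pd.DataFrame  # columns wdg, evc, bet, clo, rank_*
    weight_scheme: str
    condition: str = ""
    p_threshold: float | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.table.index)


def _eigenvector_by_component(g: nx.Graph, attr: str) -> dict[str, float]:
    """Principal eigenvector of the weighted adjacency, per component,
    each component scaled to max 1; isolated nodes score 0."""
    scores: dict[str, float] = {n: 0.0 for n in g.nodes}
    for comp in nx.connected_components(g):
        comp = list(comp)
        if len(comp) == 1:
            continue
        A = nx.to_numpy_array(g, nodelist=comp, weight=attr)
        vals, vecs = np.linalg.eigh(A)
        v = np.abs(vecs[:, -1])
        v = v / v.max()
        for n, s in zip(comp, v):
            scores[n] = float(s)
    return scores


def centralities(
    net: FunctionalNetwork, weight_scheme: str = "r"
) -> CentralityTable:
    """Weighted degree, eigenvector, betweenness and closeness per node.

    Wdg sums edge weights (r by default; the Fisher z alternative is
    available).  Bet and Clo use unweighted shortest paths; Clo for node
    i is (number of reachable nodes) / (sum of distances to them).
    """
    g = net.graph
    nodes = net.regions
    attr = _weight_attr(weight_scheme) or "weight"

    wdg = pd.Series(dict(g.degree(weight=attr)), dtype=float).reindex(nodes)
    evc = pd.Series(_eigenvector_by_component(g, attr)).reindex(nodes)

    # betweenness via igraph (identical to Brandes counts, unnormalized)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    igg = ig.Graph(n=len(nodes), edges=edges)
    bet = pd.Series(igg.betweenness(directed=False), index=nodes, dtype=float)

    dist, _ = distance_matrix(net)
    finite = np.isfinite(dist)
    np.fill_diagonal(finite, False)
    reach = finite.sum(axis=1)
    dsum = np.where(finite, dist, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        clo = np.where(reach > 0, reach / np.where(dsum == 0, np.inf, dsum), 0.0)
    clo = pd.Series(clo, index=nodes, dtype=float)

    table = pd.DataFrame({"wdg": wdg, "evc": evc, "bet": bet, "clo": clo})
    for m in MEASURES:
        table[f"rank_{m}"] = table[m].rank(ascending=False, method="min").astype(int)
    return CentralityTable(table, weight_scheme, net.condition, net.p_threshold)


@dataclass
class HubResult:
    """Top-quartile flags per measure and the resulting hub set."""

    hubs: set[str]
    top_sets: dict[str, set[str]]
    table: pd.DataFrame
    top_fraction: float
    min_measures: int
    tie_expansions: dict[str, int]


def identify_hubs(
    table: CentralityTable, top_fraction: float = 0.25, min_measures: int = 3
) -> HubResult:
    """Nodes in the top quartile of at least ``min_measures`` measures.

    Per measure the top floor(N * top_fraction) nodes by value are
    flagged (ties broken by value then lexicographic code); ties exactly
    at the cutoff value expand the list, with the expansion size
    recorded.
    """
    tab = table.table.copy()
    n = len(tab)
    k = math.floor(n * top_fraction)
    top_sets: dict[str, set[str]] = {}
    expansions: dict[str, int] = {}
    for m in MEASURES:
        ordered = tab[m].loc[sorted(tab.index)].sort_values(ascending=False, kind="mergesort")
        if k == 0:
            top_sets[m] = set()
            expansions[m] = 0
            continue
        cutoff = ordered.iloc[k - 1]
        chosen = ordered[ordered >= cutoff].index.tolist()
        expansions[m] = max(0, len(chosen) - k)
        top_sets[m] = set(chosen)
        tab[f"top_{m}"] = tab.index.isin(top_sets[m])
    counts = sum(tab.get(f"top_{m}", pd.Series(False, index=tab.index)).astype(int) for m in MEASURES)
    tab["n_top_measures"] = counts
    tab["hub"] = counts >= min_measures
    hubs = set(tab.index[tab["hub"]])
    if any(expansions.values()):
        warnings.warn(f"top-quartile ties expanded the lists: {expansions}", stacklevel=2)
    return HubResult(hubs, top_sets, tab, top_fraction, min_measures, expansions)


def stable_hubs(*hub_sets: set[str]) -> set[str]:
    """Intersection of hub sets across threshold levels."""
    if len(hub_sets) < 2:
        raise ValueError("need at least two hub sets to intersect")
    out = set(hub_sets[0])
    for s in hub_sets[1:]:
        out &= set(s)
    return out
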