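"""Independent brute-force reference implementations for graph measures.

Everything here works from the raw adjacency structure with elementary
algorithms (BFS layers, triangle enumeration, power iteration, explicit
partition enumeration) so the package's networkx/igraph-backed measures
can be checked against a second, independent route.  Deliberately slow; for
graphs of about a dozen nodes.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj: dict, source):
    """Unweighted shortest-path distances from source (dict node -> d)."""
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def all_pairs_distances(adj: dict) -> dict:
    return {u: bfs_distances(adj, u) for u in adj}


def shortest_path_counts(adj: dict, source):
    """Number of distinct shortest paths from source to every node."""
    dist = bfs_distances(adj, source)
    sigma = {u: 0 for u in adj}
    sigma[source] = 1
    for u in sorted(dist, key=dist.get):
        for v in adj[u]:
            if dist.get(v, None) == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def betweenness(adj: dict) -> dict:
    """Unnormalized betweenness: sum over pairs of the fraction of
    shortest s-t paths passing through v (pair counted once)."""
    nodes = list(adj)
    bet = {v: 0.0 for v in nodes}
    dists = {}
    sigmas = {}
    for s in nodes:
        dists[s], sigmas[s] = shortest_path_counts(adj, s)
    for s, t in itertools.combinations(nodes, 2):
        if t not in dists[s]:
            continue
        d_st = dists[s][t]
        n_st = sigmas[s][t]
        for v in nodes:
            if v in (s, t) or t not in dists[s]:
                continue
            if v in dists[s] and t in dists[v] and dists[s][v] + dists[v][t] == d_st:
                bet[v] += sigmas[s][v] * sigmas[v][t] / n_st
    return bet


def closeness(adj: dict) -> dict:
    """(number of reachable nodes) / (sum of distances to them); 0 if none."""
    out = {}
    for u in adj:
        dist = bfs_distances(adj, u)
        del dist[u]
        out[u] = len(dist) / sum(dist.values()) if dist else 0.0
    return out


def nodal_efficiency(adj: dict) -> dict:
    n = len(adj)
    out = {}
    for u in adj:
        dist = bfs_distances(adj, u)
        del dist[u]
        out[u] = sum(1.0 / d for d in dist.values()) / (n - 1) if n > 1 else 0.0
    return out


def global_efficiency(adj: dict) -> float:
    eff = nodal_efficiency(adj)
    return sum(eff.values()) / len(eff) if eff else 0.0


def average_path_length(adj: dict) -> float:
    ds = []
    for u, v in itertools.combinations(adj, 2):
        dist = bfs_distances(adj, u)
        if v in dist:
            ds.append(dist[v])
    return float(np.mean(ds)) if ds else float("nan")


def clustering(adj: dict) -> dict:
    """Triangle count over possible neighbor pairs, per node."""
    out = {}
    for u in adj:
        nbrs = list(adj[u])
        k = len(nbrs)
        if k < 2:
            out[u] = 0.0
            continue
        tri = sum(1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a])
        out[u] = tri / (k * (k - 1) / 2)
    return out


def weighted_degree(weights: dict) -> dict:
    """weights: {(u, v): w} undirected."""
    out = {}
    for (u, v), w in weights.items():
        out[u] = out.get(u, 0.0) + w
        out[v] = out.get(v, 0.0) + w
    return out


def eigenvector_power(adj_matrix: np.ndarray, n_iter: int = 20000, tol: float = 1e-14) -> np.ndarray:
    """Principal (Perron) eigenvector of a component's adjacency by power
    iteration.  A diagonal shift makes the Perron root strictly dominant
    (bipartite components have eigenvalues in +/- pairs), without
    changing the eigenvectors."""
    n = len(adj_matrix)
    shifted = adj_matrix + np.eye(n) * (adj_matrix.sum(axis=1).max() + 1.0)
    v = np.ones(n) / np.sqrt(n)
    for _ in range(n_iter):
        nv = shifted @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            return np.zeros(n)
        nv = nv / norm
        if np.abs(nv - v).max() < tol:
            v = nv
            break
        v = nv
    return np.abs(v)


def components(adj: dict) -> list[list]:
    seen = set()
    comps = []
    for u in adj:
        if u in seen:
            continue
        comp = list(bfs_distances(adj, u))
        seen.update(comp)
        comps.append(comp)
    return comps


def wc_zscore_oracle(adj: dict, membership: dict) -> dict:
    kappa = {
        u: sum(1 for v in adj[u] if membership[v] == membership[u]) for u in adj
    }
    out = {}
    for c in set(membership.values()):
        nodes = [u for u in adj if membership[u] == c]
        ks = np.array([kappa[u] for u in nodes], dtype=float)
        mu, sd = ks.mean(), ks.std()
        for u in nodes:
            out[u] = 0.0 if sd == 0 else (kappa[u] - mu) / sd
    return out


def participation_oracle(adj: dict, membership: dict, variant: str) -> dict:
    out = {}
    for u in adj:
        k = len(adj[u])
        if k == 0:
            out[u] = 0.0
            continue
        per = {}
        for v in adj[u]:
            per[membership[v]] = per.get(membership[v], 0) + 1
        if variant == "guimera":
            out[u] = 1.0 - sum((c / k) ** 2 for c in per.values())
        else:
            out[u] = 1.0 - per.get(membership[u], 0) / k
    return out


def modularity(weights: dict, nodes: list, membership: dict) -> float:
    """Q from the weighted adjacency and a membership map."""
    two_m = 2.0 * sum(weights.values())
    if two_m == 0:
        return 0.0
    strength = {u: 0.0 for u in nodes}
    for (u, v), w in weights.items():
        strength[u] += w
        strength[v] += w
    q = 0.0
    for (u, v), w in weights.items():
        if membership[u] == membership[v]:
            q += 2 * w / two_m
    for u in nodes:
        for v in nodes:
            if membership[u] == membership[v]:
                q -= strength[u] * strength[v] / (two_m**2)
    return q


def set_partitions(items: list):
    """Every partition of items into nonempty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def best_modularity_partition(weights: dict, nodes: list) -> tuple[float, list]:
    best_q, best = -np.inf, None
    for part in set_partitions(nodes):
        membership = {u: i for i, block in enumerate(part) for u in block}
        q = modularity(weights, nodes, membership)
        if q > best_q + 1e-12:
            best_q, best = q, part
    return best_q, best
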