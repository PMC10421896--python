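import numpy as np
import pandas as pd
import pytest

import fosnet
from fosnet.data_model import ConditionDesign, ExpressionMatrix, RegionAtlas
from fosnet.network import FunctionalNetwork

import networkx as nx


@pytest.fixture(scope="session")
def atlas() -> RegionAtlas:
    return fosnet.default_atlas()


@pytest.fixture(scope="session")
def study_cohort(atlas):
    """One deterministic study-like synthetic cohort plus its design."""
    expr = fosnet.generate_cohort(fosnet.study_like_spec(seed=7))
    design = fosnet.study_design()
    return expr, design


@pytest.fixture(scope="session")
def normalized_cohort(study_cohort):
    expr, design = study_cohort
    return fosnet.normalize_to_baseline(expr, design), design


@pytest.fixture
def tiny_atlas() -> RegionAtlas:
    table = pd.DataFrame(
        {
            "code": ["R1", "R2", "R3", "R4", "R5", "R6"],
            "name": [f"region {i}" for i in range(1, 7)],
            "group": ["AMY", "AMY", "AMY", "DH", "DH", "PFC"],
        }
    )
    return RegionAtlas(table)


def make_expression(values: np.ndarray, conditions: list[str], atlas: RegionAtlas) -> ExpressionMatrix:
    ids = [f"a{i:02d}" for i in range(len(conditions))]
    df = pd.DataFrame(values, index=ids, columns=atlas.codes[: values.shape[1]])
    return ExpressionMatrix(df, pd.Series(conditions, index=ids), atlas.subset(codes=list(df.columns)))


def net_from_graph(g: nx.Graph, condition: str = "X", p_threshold: float = 0.05) -> FunctionalNetwork:
    """Wrap an arbitrary weighted graph as a FunctionalNetwork for topology tests."""
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        w = d.get("weight", 0.5)
        h.add_edge(u, v, weight=w, z=float(np.arctanh(min(w, 1 - 1e-12))))
    return FunctionalNetwork(condition, p_threshold, h, 0)


def random_weighted_graph(rng: np.random.Generator, n: int, p_edge: float = 0.4) -> nx.Graph:
    g = nx.Graph()
    nodes = [f"n{i:02d}" for i in range(n)]
    g.add_nodes_from(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                g.add_edge(nodes[i], nodes[j], weight=float(rng.uniform(0.05, 0.95)))
    return g


def adjacency_dict(g: nx.Graph) -> dict:
    return {u: set(g.neighbors(u)) for u in g.nodes}
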