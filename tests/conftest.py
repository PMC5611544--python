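import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexnet.clustering import ClusterSet


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, log2-scale."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [2.0, 2.5, 2.0, 2.5]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def two_triangles():
    """Two disjoint unit-weight triangles."""
    graph = nx.Graph()
    for tri in (("a", "b", "c"), ("x", "y", "z")):
        for i in range(3):
            graph.add_edge(tri[i], tri[(i + 1) % 3], weight=1.0)
    return graph


@pytest.fixture
def triangle_clusters(two_triangles):
    return ClusterSet([("a", "b", "c"), ("x", "y", "z")], [], t_d=0.5)


def random_weighted_graph(seed, n_nodes=20, p_edge=0.3):
    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    graph.add_nodes_from(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                graph.add_edge(nodes[i], nodes[j], weight=rng.random())
    return graph
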