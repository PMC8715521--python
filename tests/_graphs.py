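"""Small weighted graphs with known community structure, shared across tests."""

import networkx as nx


def _clique(nodes):
    return [(i, j, 1.0) for i in nodes for j in nodes if i < j]


def build(edges, n):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


ORACLE_GRAPHS = {
    "single-edge-pair": build([(0, 1, 1.0)], 2),
    "two-4cliques-bridged": build(_clique(range(4)) + _clique(range(4, 8))
                                  + [(0, 4, 0.5)], 8),
    "edgeless-5": build([], 5),
    "triangle-plus-tail": build([(0, 1, 1), (1, 2, 1), (0, 2, 1), (2, 3, 0.6),
                                 (3, 4, 0.9)], 5),
    "star-6": build([(0, i, 1.0) for i in range(1, 6)], 6),
    "weighted-path-7": build([(i, i + 1, 0.5 + 0.1 * i) for i in range(6)], 7),
    "clique-with-isolates": build(_clique(range(4)), 7),
}
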