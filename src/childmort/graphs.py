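"""County adjacency graphs.

The spatial prior of the smoother and the spatial component of the synthetic
mortality surface both live on an undirected contiguity graph over
administrative units ("counties").  Nodes carry opaque string identifiers;
edges are unordered pairs.  Graphs must be connected, loop-free and have at
least two nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected, connected contiguity graph over counties.

    Parameters
    ----------
    node_ids : tuple of str
        Ordered county identifiers; the order fixes the row/column order of
        every matrix built from the graph.
    edges : frozenset of (str, str)
        Unordered node pairs, stored sorted within each pair.
    """

    node_ids: tuple
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        ids = tuple(str(n) for n in self.node_ids)
        object.__setattr__(self, "node_ids", ids)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate node ids")
        if len(ids) < 2:
            raise ValueError("graph must have at least 2 nodes (K >= 2)")
        norm = set()
        known = set(ids)
        for a, b in self.edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-loop at node {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
            norm.add((a, b) if a < b else (b, a))
        object.__setattr__(self, "edges", frozenset(norm))
        if not nx.is_connected(self.to_networkx()):
            raise ValueError("graph is not connected")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index(self, node_id: str) -> int:
        return self.node_ids.index(str(node_id))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g

    def adjacency_matrix(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix W in node_ids order."""
        pos = {n: i for i, n in enumerate(self.node_ids)}
        W = np.zeros((self.n_nodes, self.n_nodes))
        for a, b in self.edges:
            i, j = pos[a], pos[b]
            W[i, j] = W[j, i] = 1.0
        return W

    def degrees(self) -> np.ndarray:
        return self.adjacency_matrix().sum(axis=1)


def make_lattice_adjacency(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-contiguity lattice graph with ``rows * cols`` counties.

    Serves as a stand-in for a real county contiguity map in simulations
    and tests.  Node ids are ``c01, c02, ...`` in row-major order.
    """
    rows, cols = int(rows), int(cols)
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ValueError("lattice must have at least 2 cells")
    n = rows * cols
    ids = tuple(f"c{i + 1:02d}" for i in range(n))
    grid = nx.grid_2d_graph(rows, cols)
    edges = set()
    for (r1, c1), (r2, c2) in grid.edges():
        i, j = r1 * cols + c1, r2 * cols + c2
        a, b = ids[i], ids[j]
        edges.add((a, b) if a < b else (b, a))
    return AdjacencyGraph(ids, frozenset(edges))


def write_edge_list(graph: AdjacencyGraph, path) -> None:
    """Write edges as two whitespace-separated node ids per line.

    Isolated nodes cannot occur (graphs are connected), so the edge list
    fully determines the graph up to node order; node order is recovered
    by sorting on read.
    """
    with open(path, "w") as fh:
        for a, b in sorted(graph.edges):
            fh.write(f"{a} {b}\n")


def read_edge_list(path) -> AdjacencyGraph:
    edges = set()
    nodes = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two node ids, got {line!r}")
            a, b = parts
            nodes.update((a, b))
            edges.add((a, b) if a < b else (b, a))
    return AdjacencyGraph(tuple(sorted(nodes)), frozenset(edges))
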