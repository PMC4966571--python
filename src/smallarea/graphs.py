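"""Census-tract contiguity graphs.

Tract adjacency enters the analysis only through an undirected contiguity
graph (who neighbours whom), which is all the intrinsic CAR prior needs.
Graphs are plain :class:`networkx.Graph` objects whose nodes are integer
tract identifiers ``0..n-1``; helper functions below provide the derived
structure (Laplacian, connected components) in a fixed node order.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "make_city_lattice",
    "node_order",
    "laplacian",
    "connected_components",
    "write_edgelist",
    "read_edgelist",
]


def make_city_lattice(n_rows: int, n_cols: int) -> nx.Graph:
    """Rook-contiguity rectangular lattice of ``n_rows x n_cols`` tracts.

    Stands in for real census-tract contiguity: every tract neighbours the
    tracts directly above/below/left/right of it.  The result is connected,
    simple and undirected, with nodes relabelled ``0..n_rows*n_cols-1`` in
    row-major order.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError(f"lattice dimensions must be >= 1, got {n_rows}x{n_cols}")
    g = nx.grid_2d_graph(int(n_rows), int(n_cols))
    return nx.convert_node_labels_to_integers(g, ordering="sorted")


def node_order(graph: nx.Graph) -> list:
    """Canonical (sorted) node order used for all vector representations."""
    return sorted(graph.nodes())


def laplacian(graph: nx.Graph) -> np.ndarray:
    """Dense graph Laplacian ``D - A`` in canonical node order."""
    return nx.laplacian_matrix(graph, nodelist=node_order(graph)).toarray().astype(float)


def connected_components(graph: nx.Graph) -> list[np.ndarray]:
    """Connected components as index arrays into the canonical node order."""
    order = node_order(graph)
    pos = {v: i for i, v in enumerate(order)}
    return [
        np.array(sorted(pos[v] for v in comp), dtype=int)
        for comp in nx.connected_components(graph)
    ]


def write_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """Write adjacency as a two-column whitespace-separated edge list."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# nodes: {graph.number_of_nodes()}\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u} {v}\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    """Read a two-column edge list written by :func:`write_edgelist`.

    The ``# nodes:`` header preserves isolated tracts (nodes without edges).
    """
    path = Path(path)
    g = nx.Graph()
    n_nodes = None
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "nodes:" in line:
                    n_nodes = int(line.split("nodes:")[1])
                continue
            u, v = line.split()
            g.add_edge(int(u), int(v))
    if n_nodes is not None:
        g.add_nodes_from(range(n_nodes))
    return g
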