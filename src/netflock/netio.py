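"""Plain-text network I/O.

Edge lists are whitespace-separated ``i j`` pairs (0-based), one per line,
with an optional third column carrying the bond rest length. The
reader/writer round-trip is exact (rest lengths are written with 17
significant digits).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .exceptions import InvalidInputError
from .network import InteractionNetwork


def write_edge_list(network: InteractionNetwork, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if network.rest_lengths is None:
            for i, j in network.edges:
                fh.write(f"{i} {j}\n")
        else:
            for (i, j), l in zip(network.edges, network.rest_lengths):
                fh.write(f"{i} {j} {l:.17g}\n")


def read_edge_list(path, n_nodes: int | None = None) -> InteractionNetwork:
    """Read an edge list; ``n_nodes`` defaults to ``max index + 1``."""
    path = Path(path)
    edges = []
    rests = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (2, 3):
                raise InvalidInputError(f"{path}:{ln}: expected 'i j [rest_length]'")
            edges.append((int(parts[0]), int(parts[1])))
            if len(parts) == 3:
                rests.append(float(parts[2]))
    if rests and len(rests) != len(edges):
        raise InvalidInputError(f"{path}: rest lengths present on only some lines")
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if n_nodes is None:
        n_nodes = int(edges.max()) + 1 if edges.size else 1
    return InteractionNetwork(n_nodes, edges, np.asarray(rests) if rests else None)


def to_networkx(network: InteractionNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(network.n_nodes))
    if network.rest_lengths is None:
        g.add_edges_from(map(tuple, network.edges))
    else:
        triples = (
            (int(i), int(j), float(l))
            for (i, j), l in zip(network.edges, network.rest_lengths)
        )
        g.add_weighted_edges_from(triples, weight="rest_length")
    return g


def write_graphml(network: InteractionNetwork, path) -> None:
    """GraphML export for external visualization tools."""
    nx.write_graphml(to_networkx(network), str(path))
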