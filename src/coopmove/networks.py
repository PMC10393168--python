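"""Place networks individuals move on.

The population lives on a network of *M* places (one individual homed per
place, so M = N).  Three symmetric topologies are built in — complete,
circle and star — and arbitrary simple connected graphs can be supplied as
plain edge lists.  The place network is distinct from the *evolutionary
graph* of replacement weights between individuals (see
:mod:`coopmove.replacement`); here nodes are locations, not individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = ["PlaceNetwork", "build_network", "read_edge_list", "write_edge_list"]

TOPOLOGIES = ("complete", "circle", "star")


@dataclass(frozen=True)
class PlaceNetwork:
    """A simple connected graph of places, stored in CSR adjacency form.

    Places are integer-labelled ``0 .. M-1``.  For the star topology the hub
    is place ``0`` by convention.

    Attributes
    ----------
    M : int
        Number of places.
    adj_indptr, adj_indices : ndarray of int64
        CSR layout: the neighbours of place ``m`` are
        ``adj_indices[adj_indptr[m]:adj_indptr[m+1]]``.
    degrees : ndarray of int64
        ``degrees[m]`` is the number of neighbours of place ``m``.
    topology_tag : str
        One of ``complete | circle | star | custom``.
    """

    M: int
    adj_indptr: np.ndarray
    adj_indices: np.ndarray
    degrees: np.ndarray
    topology_tag: str = "custom"

    def neighbors(self, m: int) -> np.ndarray:
        """Places adjacent to ``m`` (sorted ndarray of length ``degree(m)``)."""
        self._check_place(m)
        return self.adj_indices[self.adj_indptr[m] : self.adj_indptr[m + 1]]

    def degree(self, m: int) -> int:
        self._check_place(m)
        return int(self.degrees[m])

    def _check_place(self, m: int) -> None:
        if not (0 <= m < self.M):
            raise ValueError(f"unknown place {m!r}; valid places are 0..{self.M - 1}")

    @property
    def n_edges(self) -> int:
        return int(self.degrees.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.M))
        for m in range(self.M):
            for j in self.neighbors(m):
                g.add_edge(m, int(j))
        return g

    def edge_list(self) -> list[tuple[int, int]]:
        """Edges as sorted (u, v) pairs with u < v."""
        return sorted(
            (m, int(j)) for m in range(self.M) for j in self.neighbors(m) if m < j
        )


def _from_networkx(g: nx.Graph, topology_tag: str) -> PlaceNetwork:
    M = g.number_of_nodes()
    if set(g.nodes) != set(range(M)):
        raise ValueError("places must be labelled 0..M-1 with no gaps")
    if any(g.has_edge(m, m) for m in g.nodes):
        raise ValueError("self-edges are not allowed")
    if M >= 2 and not nx.is_connected(g):
        raise ValueError("place network must be connected")
    indptr = np.zeros(M + 1, dtype=np.int64)
    neigh = [np.array(sorted(g.neighbors(m)), dtype=np.int64) for m in range(M)]
    degrees = np.array([len(a) for a in neigh], dtype=np.int64)
    indptr[1:] = np.cumsum(degrees)
    indices = np.concatenate(neigh) if M else np.empty(0, dtype=np.int64)
    return PlaceNetwork(M, indptr, indices, degrees, topology_tag)


def build_network(topology: str, M: int) -> PlaceNetwork:
    """Build one of the named topologies with ``M`` places.

    ``complete`` requires M >= 2, ``circle`` M >= 3, ``star`` M >= 2
    (hub is place 0).
    """
    if topology == "complete":
        if M < 2:
            raise ValueError("complete network requires M >= 2")
        g = nx.complete_graph(M)
    elif topology == "circle":
        if M < 3:
            raise ValueError("circle network requires M >= 3")
        g = nx.cycle_graph(M)
    elif topology == "star":
        if M < 2:
            raise ValueError("star network requires M >= 2")
        g = nx.star_graph(M - 1)  # hub is node 0
    else:
        raise ValueError(
            f"unknown topology {topology!r}; expected one of {TOPOLOGIES} "
            "(use read_edge_list for custom networks)"
        )
    return _from_networkx(g, topology)


def custom_network(edges: Iterable[Sequence[int]]) -> PlaceNetwork:
    """Build a custom place network from (u, v) integer pairs (0-based)."""
    g = nx.Graph()
    edges = [(int(u), int(v)) for u, v in edges]
    if not edges:
        raise ValueError("edge list is empty")
    g.add_edges_from(edges)
    M = max(g.nodes) + 1
    g.add_nodes_from(range(M))
    return _from_networkx(g, "custom")


def read_edge_list(path: str | Path) -> PlaceNetwork:
    """Read a custom network from a whitespace-separated two-column edge list.

    Lines starting with ``#`` are ignored; a non-numeric first line is
    treated as a header and skipped.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            try:
                u, v = int(parts[0]), int(parts[1])
            except (ValueError, IndexError):
                if lineno == 0:
                    continue  # header
                raise ValueError(f"{path}:{lineno + 1}: expected two integers")
            edges.append((u, v))
    return custom_network(edges)


def write_edge_list(net: PlaceNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in net.edge_list():
            fh.write(f"{u} {v}\n")
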