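"""Undirected PPI networks: hubs, hub sub-networks and derived gene-sets.

A hub is a node with degree >= ``min_degree`` (default 5).  A hub sub-network
is the hub, its immediate interactors, and only the hub-interactor edges;
interactor-interactor edges are deliberately excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import scipy.sparse as sp

from .errors import FormatError

DEFAULT_MIN_DEGREE = 5


class PPINetwork:
    """Undirected, simple (no self-loops, deduplicated) gene interaction graph."""

    def __init__(self, edges=(), nodes=()):
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        n_self = 0
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                n_self += 1
                continue
            g.add_edge(u, v)
        if n_self:
            warnings.warn(f"dropped {n_self} self-loop edge(s)", stacklevel=2)
        self._g = g

    @classmethod
    def _from_graph(cls, g: nx.Graph):
        net = cls.__new__(cls)
        net._g = g
        return net

    @property
    def nodes(self) -> tuple:
        return tuple(sorted(self._g.nodes))

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> tuple:
        return tuple(sorted(tuple(sorted(e)) for e in self._g.edges))

    def __contains__(self, node):
        return node in self._g

    def degree(self, node) -> int:
        return self._g.degree[node]

    def degrees(self) -> dict:
        return {n: d for n, d in self._g.degree}

    def neighbors(self, node) -> tuple:
        return tuple(sorted(self._g.neighbors(node)))

    def subgraph(self, keep_nodes) -> "PPINetwork":
        return PPINetwork._from_graph(nx.Graph(self._g.subgraph(keep_nodes)))

    def adjacency(self, order) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix over ``order`` (must all be nodes)."""
        for n in order:
            if n not in self._g:
                raise KeyError(f"unknown network node {n!r}")
        return sp.csr_matrix(nx.to_scipy_sparse_array(self._g, nodelist=list(order), dtype=float))

    def __eq__(self, other):
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges() == other.edges()


@dataclass(frozen=True)
class HubSubnetwork:
    """A hub, its immediate interactors, and the hub-interactor edges only."""

    hub: str
    interactors: tuple

    @property
    def edges(self) -> tuple:
        return tuple((self.hub, i) for i in self.interactors)

    @property
    def n_edges(self) -> int:
        return len(self.interactors)


@dataclass(frozen=True)
class GeneSet:
    """An unordered set of genes named after the hub it came from."""

    set_id: str
    members: tuple

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene-set {self.set_id!r} has duplicate members")


def read_edge_list(path) -> PPINetwork:
    """Read a two-column TSV edge list or a three-column SIF file.

    In SIF form (``geneA<TAB>interaction<TAB>geneB``) the middle column is
    ignored.  Lines with any other number of fields raise :class:`FormatError`.
    """
    edges = []
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated two-column files
                fields = line.split()
            if len(fields) == 2:
                edges.append((fields[0], fields[1]))
            elif len(fields) == 3:
                edges.append((fields[0], fields[2]))
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 fields (edge list) or 3 (SIF), "
                    f"got {len(fields)}"
                )
    if n_lines == 0:
        warnings.warn(f"{path}: empty network file; returning empty network", stacklevel=2)
    return PPINetwork(edges)


def write_edge_list(net: PPINetwork, path):
    with open(path, "w") as fh:
        for u, v in net.edges():
            fh.write(f"{u}\t{v}\n")


def find_hubs(net: PPINetwork, min_degree: int = DEFAULT_MIN_DEGREE) -> list:
    """All genes with degree >= min_degree, sorted by (degree desc, gene id asc)."""
    if min_degree < 1:
        raise ValueError("min_degree must be a positive integer")
    deg = net.degrees()
    hubs = [n for n, d in deg.items() if d >= min_degree]
    return sorted(hubs, key=lambda n: (-deg[n], n))


def hub_subnetworks(net: PPINetwork, hubs) -> list:
    """One :class:`HubSubnetwork` per hub (interactor-interactor edges excluded)."""
    subnets = []
    for h in hubs:
        if h not in net:
            raise KeyError(f"unknown hub {h!r}")
        subnets.append(HubSubnetwork(hub=str(h), interactors=net.neighbors(h)))
    return subnets


def subnetworks_to_genesets(subnets) -> list:
    """Forget the edges: each sub-network becomes the set {hub} + interactors."""
    return [
        GeneSet(set_id=s.hub, members=tuple(sorted((s.hub, *s.interactors))))
        for s in subnets
    ]
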