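"""Pathway networks as undirected, unweighted graphs.

A pathway is represented by its gene nodes and the undirected edges between
them.  A node may contain several member genes (e.g. a "STAT*" node holding
the whole STAT family); membership is carried alongside the graph so that
expression aggregation can happen upstream.  Shortest path length in edge
steps is the only notion of distance used: two nodes one step apart interact
directly, and longer paths stand in for progressively less likely molecular
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "PathwayNetwork",
    "PathDistanceMatrix",
    "HubAnnotation",
    "build_network",
    "path_lengths",
    "annotate_hubs",
    "remove_node",
]


@dataclass(frozen=True)
class PathwayNetwork:
    """Undirected pathway graph over named gene nodes.

    Attributes
    ----------
    node_ids
        Unique node identifiers in a fixed order; all matrices elsewhere in
        the package are aligned to this order.
    node_members
        Mapping of node id to the member gene symbols it contains (at least
        one per node; single-member nodes map to themselves).
    edges
        Set of undirected edges stored as sorted ``(u, v)`` tuples.
    """

    node_ids: tuple[str, ...]
    node_members: dict[str, tuple[str, ...]]
    edges: frozenset[tuple[str, str]]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.node_ids)}
        )

    @property
    def M(self) -> int:
        """Number of nodes."""
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix aligned to ``node_ids``."""
        A = np.zeros((self.M, self.M), dtype=np.uint8)
        for u, v in self.edges:
            i, j = self._index[u], self._index[v]
            A[i, j] = A[j, i] = 1
        return A

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1).astype(int)

    def to_networkx(self):
        """Export as a :class:`networkx.Graph` (isolated nodes included)."""
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.node_ids)
        G.add_edges_from(self.edges)
        return G


@dataclass(frozen=True)
class PathDistanceMatrix:
    """All-pairs shortest path lengths in edge steps.

    ``d[j, k]`` is the minimum number of edges between nodes j and k;
    ``inf`` marks pairs with no connecting path, 0 the diagonal.
    """

    node_ids: tuple[str, ...]
    d: np.ndarray


@dataclass(frozen=True)
class HubAnnotation:
    """Node degrees and the hub set ``{j : degree[j] >= hub_threshold}``."""

    degree: dict[str, int]
    hub_threshold: int
    hubs: frozenset[str]


def build_network(
    edges,
    node_members: dict[str, list[str] | tuple[str, ...]] | None = None,
) -> PathwayNetwork:
    """Build a :class:`PathwayNetwork` from an edge list.

    Parameters
    ----------
    edges
        Iterable of ``(u, v)`` node-id pairs.  Duplicate edges (in either
        orientation) are collapsed; self-loops are rejected.
    node_members
        Optional map node id -> member gene symbols.  Nodes appearing only
        here (no incident edge) are kept as isolated nodes.

    Node order is first appearance in the edge list, then any
    members-only nodes in their mapping order.
    """
    seen: dict[str, None] = {}
    edge_set: set[tuple[str, str]] = set()
    for u, v in edges:
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"self-loop on node {u!r} is not allowed")
        seen.setdefault(u)
        seen.setdefault(v)
        edge_set.add((u, v) if u <= v else (v, u))
    if node_members:
        for n in node_members:
            seen.setdefault(str(n))
    if not seen:
        raise ValueError("network has no nodes")
    node_ids = tuple(seen)
    members = {
        n: tuple(node_members[n]) if node_members and n in node_members else (n,)
        for n in node_ids
    }
    for n, m in members.items():
        if len(m) == 0:
            raise ValueError(f"node {n!r} has an empty member list")
    return PathwayNetwork(node_ids=node_ids, node_members=members, edges=frozenset(edge_set))


def path_lengths(net: PathwayNetwork) -> PathDistanceMatrix:
    """Breadth-first all-pairs shortest path lengths in edge counts."""
    A = csr_matrix(net.adjacency())
    d = shortest_path(A, method="D", unweighted=True, directed=False)
    return PathDistanceMatrix(node_ids=net.node_ids, d=d)


def annotate_hubs(net: PathwayNetwork, hub_threshold: int = 3) -> HubAnnotation:
    """Degrees and hub status (degree at or above ``hub_threshold``)."""
    if hub_threshold < 1:
        raise ValueError("hub_threshold must be >= 1")
    deg = net.degrees()
    degree = {n: int(k) for n, k in zip(net.node_ids, deg)}
    hubs = frozenset(n for n, k in degree.items() if k >= hub_threshold)
    return HubAnnotation(degree=degree, hub_threshold=hub_threshold, hubs=hubs)


def remove_node(net: PathwayNetwork, j: str) -> PathwayNetwork:
    """Return a new network with node ``j`` and its incident edges deleted.

    The input network is left unmodified; this is the elementary step of the
    leave-one-out influence evaluation.
    """
    if j not in net._index:
        raise KeyError(f"unknown node {j!r}")
    node_ids = tuple(n for n in net.node_ids if n != j)
    if not node_ids:
        raise ValueError("cannot remove the only node in the network")
    members = {n: net.node_members[n] for n in node_ids}
    edges = frozenset(e for e in net.edges if j not in e)
    return PathwayNetwork(node_ids=node_ids, node_members=members, edges=edges)
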