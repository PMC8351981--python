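"""Multilayer (multiplex) network data model and edge-list I/O.

A multilayer network is a single universe of node labels connected by several
undirected, unweighted edge sets ("layers").  Same-label nodes in different
layers are implicitly coupled counterparts; there are no explicit inter-layer
edge records.  A node may be present-but-isolated in a layer, or absent from
it entirely.

The on-disk format is a UTF-8 TSV with three columns ``layer  node_a  node_b``
(optional header, ``#``-prefixed comment lines).  Isolated nodes, which a pure
edge list cannot express, are carried by ``#nodes`` comment-directives::

    #nodes<TAB><layer><TAB><label>    node present but isolated in <layer>
    #nodes<TAB>-<TAB><label>          node in the universe, in no layer
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator

__all__ = [
    "MultilayerNetwork",
    "GroundTruth",
    "EdgeListParseError",
    "read_multilayer_edgelist",
    "write_multilayer_edgelist",
    "read_communities",
    "write_communities",
]

_HEADER_TOKENS = ("layer", "node_a", "node_b")


class EdgeListParseError(ValueError):
    """Raised when a multilayer edge list cannot be parsed."""


class MultilayerNetwork:
    """Node universe plus named layers of undirected edges.

    Node labels are opaque strings; iteration order of nodes and layers is
    insertion order, which makes seeded stochastic runs reproducible.
    """

    def __init__(self) -> None:
        self._nodes: dict[str, None] = {}  # insertion-ordered set
        self._layers: dict[str, None] = {}
        # adjacency: layer -> node -> set of neighbor labels (both directions)
        self._adj: dict[str, dict[str, set[str]]] = {}
        # nodes present in each layer (from edges or #nodes directives)
        self._presence: dict[str, dict[str, None]] = {}

    # -- construction ------------------------------------------------------

    def add_node(self, label: str, layer: str | None = None) -> None:
        """Add *label* to the universe, and optionally to a layer's presence."""
        self._nodes.setdefault(label, None)
        if layer is not None:
            if layer not in self._layers:
                self.add_layer(layer)
            self._presence[layer].setdefault(label, None)

    def add_layer(self, name: str) -> None:
        if name not in self._layers:
            self._layers[name] = None
            self._adj[name] = {}
            self._presence[name] = {}

    def add_edge(self, layer: str, u: str, v: str) -> None:
        """Add undirected edge (u, v) to *layer*; self-loops are rejected."""
        if u == v:
            raise ValueError(f"self-loop edge ({u!r}, {u!r}) is not allowed")
        self.add_layer(layer)
        self.add_node(u, layer)
        self.add_node(v, layer)
        self._adj[layer].setdefault(u, set()).add(v)
        self._adj[layer].setdefault(v, set()).add(u)

    # -- basic queries -----------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        """Node universe in insertion order."""
        return list(self._nodes)

    @property
    def layers(self) -> list[str]:
        """Layer names in insertion order."""
        return list(self._layers)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_layers(self) -> int:
        return len(self._layers)

    def node_presence(self, layer: str) -> set[str]:
        """Nodes present (possibly isolated) in *layer*."""
        self._check_layer(layer)
        return set(self._presence[layer])

    def has_node(self, label: str) -> bool:
        return label in self._nodes

    def has_edge(self, layer: str, u: str, v: str) -> bool:
        self._check_layer(layer)
        return v in self._adj[layer].get(u, ())

    def neighbors(self, i: str, layer: str) -> set[str]:
        """Γ_l(i): the neighbor set of node *i* in *layer*.

        Empty when *i* is isolated in, or absent from, the layer.
        """
        self._check_node(i)
        self._check_layer(layer)
        return set(self._adj[layer].get(i, ()))

    def degree(self, i: str, layer: str) -> int:
        self._check_node(i)
        self._check_layer(layer)
        return len(self._adj[layer].get(i, ()))

    def edges(self, layer: str) -> Iterator[tuple[str, str]]:
        """Undirected edges of *layer*, each pair yielded once.

        Pairs are canonicalized and ordered by node insertion order.
        """
        self._check_layer(layer)
        index = {v: i for i, v in enumerate(self._nodes)}
        seen: set[tuple[str, str]] = set()
        for u in self._presence[layer]:
            # adjacency sets iterate in hash order, which is salted per
            # process; order by insertion index so edge order (and any RNG
            # stream consumed while iterating edges) is reproducible
            for v in sorted(self._adj[layer].get(u, ()), key=index.__getitem__):
                pair = (u, v) if index[u] < index[v] else (v, u)
                if pair not in seen:
                    seen.add(pair)
                    yield pair

    def n_edges(self, layer: str | None = None) -> int:
        if layer is not None:
            return sum(1 for _ in self.edges(layer))
        return sum(self.n_edges(l) for l in self._layers)

    def edge_weight(self, i: str, j: str) -> float:
        """ω(i, j): fraction of layers that contain edge (i, j).

        Lies in {0, 1/k, ..., 1} and is symmetric; biases the random walk
        toward structure shared across layers.
        """
        if i == j:
            raise ValueError("edge weight is undefined for a self-loop")
        self._check_node(i)
        self._check_node(j)
        count = sum(1 for l in self._layers if j in self._adj[l].get(i, ()))
        return count / self.n_layers

    def aggregate(self, name: str = "aggregate") -> "MultilayerNetwork":
        """Collapse all layers into one by edge-set union (layer aggregation).

        The node universe (and per-node presence) is preserved; the result is
        the single-layer baseline network.
        """
        agg = MultilayerNetwork()
        agg.add_layer(name)
        for v in self._nodes:
            agg.add_node(v)
        for l in self._layers:
            for v in self._presence[l]:
                agg.add_node(v, name)
            for u, v in self.edges(l):
                agg.add_edge(name, u, v)
        return agg

    # -- comparison / hashing ---------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultilayerNetwork):
            return NotImplemented
        return (
            set(self._nodes) == set(other._nodes)
            and list(self._layers) == list(other._layers)
            and all(
                # edge orientation depends on insertion order; compare pairs
                # orientation-insensitively
                {frozenset(e) for e in self.edges(l)}
                == {frozenset(e) for e in other.edges(l)}
                and self.node_presence(l) == other.node_presence(l)
                for l in self._layers
            )
        )

    def __repr__(self) -> str:
        return (
            f"MultilayerNetwork(n_nodes={self.n_nodes}, "
            f"n_layers={self.n_layers}, n_edges={self.n_edges()})"
        )

    # -- internals ---------------------------------------------------------

    def _check_node(self, label: str) -> None:
        if label not in self._nodes:
            raise KeyError(f"unknown node {label!r}")

    def _check_layer(self, name: str) -> None:
        if name not in self._layers:
            raise KeyError(f"unknown layer {name!r}")


class GroundTruth:
    """A sequence of known (planted) communities, each a set of node labels.

    Communities may overlap and need not cover the node universe.
    """

    def __init__(self, communities: Iterable[Iterable[str]]) -> None:
        self.communities: list[set[str]] = [set(c) for c in communities]
        if any(not c for c in self.communities):
            raise ValueError("ground-truth communities must be non-empty")

    def __len__(self) -> int:
        return len(self.communities)

    def __iter__(self) -> Iterator[set[str]]:
        return iter(self.communities)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return self.communities == other.communities

    def community_of(self, node: str) -> set[str]:
        """First community containing *node* (KeyError if none)."""
        for c in self.communities:
            if node in c:
                return c
        raise KeyError(f"node {node!r} is in no ground-truth community")


# -- edge-list I/O ---------------------------------------------------------


def read_multilayer_edgelist(path: str) -> MultilayerNetwork:
    """Read a layered TSV edge list into a :class:`MultilayerNetwork`.

    Duplicate and reversed-duplicate rows collapse to a single undirected
    edge.  Self-loop rows, malformed rows, and edge-free files are rejected.
    """
    net = MultilayerNetwork()
    n_edge_rows = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#"):
                _parse_directive(net, line, lineno)
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated input
                fields = line.split()
            if len(fields) != 3:
                raise EdgeListParseError(
                    f"line {lineno}: expected 3 columns (layer, node_a, "
                    f"node_b), got {len(fields)}"
                )
            if n_edge_rows == 0 and tuple(
                f.strip().lower() for f in fields
            ) == _HEADER_TOKENS:
                continue  # optional header row
            layer, u, v = (f.strip() for f in fields)
            if u == v:
                raise EdgeListParseError(
                    f"line {lineno}: self-loop edge on node {u!r}"
                )
            net.add_edge(layer, u, v)
            n_edge_rows += 1
    if n_edge_rows == 0:
        raise EdgeListParseError(f"{path}: no edges")
    return net


def _parse_directive(net: MultilayerNetwork, line: str, lineno: int) -> None:
    body = line.lstrip("#").strip()
    fields = body.split("\t")
    if not fields or fields[0] != "nodes":
        return  # plain comment
    if len(fields) != 3:
        raise EdgeListParseError(
            f"line {lineno}: malformed #nodes directive "
            "(expected '#nodes<TAB>layer<TAB>label')"
        )
    _, layer, label = (f.strip() for f in fields)
    net.add_node(label, None if layer == "-" else layer)


def write_multilayer_edgelist(net: MultilayerNetwork, path: str) -> None:
    """Write *net* as a layered TSV edge list; read-back is the identity."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("layer\tnode_a\tnode_b\n")
        edge_endpoints: dict[str, set[str]] = {l: set() for l in net.layers}
        for l in net.layers:
            for u, v in net.edges(l):
                fh.write(f"{l}\t{u}\t{v}\n")
                edge_endpoints[l].update((u, v))
        # isolated-in-layer and universe-only nodes survive via directives
        covered: set[str] = set()
        for l in net.layers:
            for v in net.node_presence(l):
                covered.add(v)
                if v not in edge_endpoints[l]:
                    fh.write(f"#nodes\t{l}\t{v}\n")
        for v in net.nodes:
            if v not in covered:
                fh.write(f"#nodes\t-\t{v}\n")


# -- communities I/O -------------------------------------------------------


def read_communities(path: str) -> GroundTruth:
    """Read a communities file: one community per line, tab-separated labels."""
    communities = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            communities.append(line.split("\t"))
    if not communities:
        raise ValueError(f"{path}: no communities")
    return GroundTruth(communities)


def write_communities(truth: GroundTruth | Iterable[Iterable[str]], path: str) -> None:
    communities = truth.communities if isinstance(truth, GroundTruth) else truth
    with open(path, "w", encoding="utf-8") as fh:
        for c in communities:
            fh.write("\t".join(sorted(c)) + "\n")
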