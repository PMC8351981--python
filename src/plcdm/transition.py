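"""Biased-walk transition probabilities for multilayer networks.

Two ingredients drive the walker:

* an **intra-layer move score** for an edge (i, j) in layer ``l``::

      P_l(i, j) = (|Γ_l(i) ∩ Γ_l(j)| + 1) / (|Γ_l(i)| + 1)
                  × 1 / (|Γ_l(j)| + 1)
                  × ω(i, j)

  favouring neighbors with many common neighbors, penalizing hubs, and
  weighting by the fraction ω of layers sharing the edge.  The score has no
  per-layer adjacency factor: it is positive for every edge that exists in
  at least one layer (ω > 0), so the walker's move support in any layer is
  the union neighborhood, while the score itself still depends on the
  current layer through the Γ_l terms.  Scores are unnormalized; they are
  rescaled to sum to one over the current node's move support at move time.

* an **inter-layer transition score** between a node's counterparts in two
  layers, a smoothed Jaccard similarity of its neighborhoods::

      R_i(l_s, l_t) = (|Γ_ls(i) ∩ Γ_lt(i)| + 1) / (|Γ_ls(i) ∪ Γ_lt(i)| + 1)

  The +1 smoothing keeps R positive even for isolated nodes, so every layer
  is always reachable.

The default edge weight is ω (fraction of shared layers); ``weight_fn`` is a
hook for alternative weightings.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np

from .network import MultilayerNetwork

__all__ = [
    "TransitionModel",
    "intra_layer_score",
    "inter_layer_score",
    "build_transition_model",
    "move_distribution",
    "layer_distribution",
]

WeightFn = Callable[[MultilayerNetwork, str, str], float]


def intra_layer_score(
    net: MultilayerNetwork,
    i: str,
    j: str,
    layer: str,
    weight_fn: WeightFn | None = None,
) -> float:
    """Unnormalized score for the walker moving i → j within *layer*.

    Zero whenever the edge exists in no layer (ω = 0).  Symmetric in (i, j).
    """
    if i == j:
        raise ValueError("intra-layer score is undefined for i == j")
    w = (weight_fn or _omega)(net, i, j)
    if w == 0.0:
        # annihilates the product; neighbor sets need not be inspected
        net.neighbors(i, layer)  # still validate node/layer arguments
        net.neighbors(j, layer)
        return 0.0
    gi = net.neighbors(i, layer)
    gj = net.neighbors(j, layer)
    common = len(gi & gj)
    return (common + 1) / (len(gi) + 1) * (1.0 / (len(gj) + 1)) * w


def _omega(net: MultilayerNetwork, i: str, j: str) -> float:
    return net.edge_weight(i, j)


def inter_layer_score(
    net: MultilayerNetwork, i: str, layer_s: str, layer_t: str
) -> float:
    """Smoothed Jaccard similarity of i's neighborhoods in two layers.

    Always in (0, 1]; equals 1 iff the neighborhoods coincide (including the
    both-empty case, where the smoothing yields 1/1).
    """
    gs = net.neighbors(i, layer_s)
    gt = net.neighbors(i, layer_t)
    return (len(gs & gt) + 1) / (len(gs | gt) + 1)


class TransitionModel:
    """Precomputed walk probabilities for one network.

    Attributes
    ----------
    intra : Mapping[str, Mapping[str, Mapping[str, float]]]
        ``intra[layer][i][j]`` — unnormalized move score, stored sparsely
        over the union edge set (the score is nonzero exactly where
        ω(i, j) > 0, regardless of the layer).
    inter : Mapping[str, numpy.ndarray]
        ``inter[i]`` — k×k matrix of inter-layer scores R_i, indexed by
        layer position; symmetric with unit diagonal.

    The model also carries flat CSR-style arrays used by the compiled walk
    kernel; these are an implementation detail.
    """

    def __init__(
        self,
        net: MultilayerNetwork,
        intra: Mapping[str, Mapping[str, Mapping[str, float]]],
        inter: Mapping[str, np.ndarray],
    ) -> None:
        self.intra = intra
        self.inter = inter
        self.node_order: list[str] = net.nodes
        self.layer_order: list[str] = net.layers
        self.node_index: dict[str, int] = {
            v: ix for ix, v in enumerate(self.node_order)
        }
        self.layer_index: dict[str, int] = {
            l: ix for ix, l in enumerate(self.layer_order)
        }
        self._build_arrays()

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    @property
    def n_layers(self) -> int:
        return len(self.layer_order)

    def _build_arrays(self) -> None:
        """Flatten per-(layer, node) neighborhoods into CSR-style arrays.

        Segment for state (layer l, node i) lives at flat index l*n + i and
        holds neighbor indices plus the cumulative renormalized move
        distribution, ready for inverse-CDF sampling.
        """
        n, k = self.n_nodes, self.n_layers
        indptr = np.zeros(n * k + 1, dtype=np.int64)
        nbr_chunks: list[np.ndarray] = []
        cum_chunks: list[np.ndarray] = []
        pos = 0
        for li, l in enumerate(self.layer_order):
            table = self.intra[l]
            for vi, v in enumerate(self.node_order):
                row = table.get(v, {})
                if row:
                    idx = np.array(
                        sorted(self.node_index[j] for j in row), dtype=np.int64
                    )
                    scores = np.array(
                        [row[self.node_order[j]] for j in idx], dtype=np.float64
                    )
                    probs = scores / scores.sum()
                    nbr_chunks.append(idx)
                    cum_chunks.append(np.cumsum(probs))
                    pos += len(idx)
                indptr[li * n + vi + 1] = pos
        self._indptr = indptr
        self._nbr = (
            np.concatenate(nbr_chunks) if nbr_chunks else np.zeros(0, np.int64)
        )
        self._cum = (
            np.concatenate(cum_chunks) if cum_chunks else np.zeros(0, np.float64)
        )
        R = np.empty((n, k, k), dtype=np.float64)
        for v, vi in self.node_index.items():
            R[vi] = self.inter[v]
        self._R = R

    def neighbor_probs(self, i: str, layer: str) -> tuple[np.ndarray, np.ndarray]:
        """(neighbor indices, renormalized move probabilities) for (i, layer)."""
        s = self.layer_index[layer] * self.n_nodes + self.node_index[i]
        lo, hi = self._indptr[s], self._indptr[s + 1]
        probs = np.diff(self._cum[lo:hi], prepend=0.0)
        return self._nbr[lo:hi], probs


def build_transition_model(
    net: MultilayerNetwork, weight_fn: WeightFn | None = None
) -> TransitionModel:
    """Compute all intra-layer scores and inter-layer matrices for *net*.

    Per layer, scores are computed for every edge of the union edge set
    (the score support, since ω > 0 there), so memory is proportional to
    k·|E_union| rather than the k·n² worst case.
    """
    wfn = weight_fn or _omega
    aggregate = net.aggregate()
    union_edges = list(aggregate.edges(aggregate.layers[0]))
    weights = {(i, j): wfn(net, i, j) for i, j in union_edges}

    intra: dict[str, dict[str, dict[str, float]]] = {}
    for l in net.layers:
        table: dict[str, dict[str, float]] = {}
        hood = {v: net.neighbors(v, l) for v in net.nodes}
        for (i, j), w in weights.items():
            if w == 0.0:
                continue
            gi, gj = hood[i], hood[j]
            score = (
                (len(gi & gj) + 1)
                / (len(gi) + 1)
                * (1.0 / (len(gj) + 1))
                * w
            )
            table.setdefault(i, {})[j] = score
            table.setdefault(j, {})[i] = score
        intra[l] = table

    k = net.n_layers
    inter: dict[str, np.ndarray] = {}
    for v in net.nodes:
        hoods = [net.neighbors(v, l) for l in net.layers]
        R = np.ones((k, k), dtype=np.float64)
        for s in range(k):
            for t in range(s + 1, k):
                r = (len(hoods[s] & hoods[t]) + 1) / (len(hoods[s] | hoods[t]) + 1)
                R[s, t] = R[t, s] = r
        inter[v] = R
    return TransitionModel(net, intra, inter)


def move_distribution(
    model: TransitionModel, net: MultilayerNetwork, i: str, layer: str
) -> dict[str, float]:
    """Move probabilities from *i* within *layer*, rescaled to sum to one.

    The support is i's union neighborhood (every j with ω(i, j) > 0); only
    a node isolated in every layer has no move at all, in which case a
    ``ValueError`` signals the degenerate "stuck" condition.
    """
    net._check_node(i)
    net._check_layer(layer)
    idx, probs = model.neighbor_probs(i, layer)
    if len(idx) == 0:
        raise ValueError(
            f"node {i!r} has no scorable neighbor in layer {layer!r} (stuck)"
        )
    return {model.node_order[j]: p for j, p in zip(idx, probs)}


def layer_distribution(
    model: TransitionModel, i: str, current_layer: str
) -> dict[str, float]:
    """Layer-change probabilities for node *i*, given its current layer.

    Proportional to R_i(current_layer, ·) over all layers (self-selection
    included); strictly positive everywhere thanks to the Jaccard smoothing.
    """
    row = model._R[model.node_index[i], model.layer_index[current_layer]]
    probs = row / row.sum()
    return {l: p for l, p in zip(model.layer_order, probs)}
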