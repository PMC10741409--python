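"""Weighted characteristic path length and clustering coefficient.

Both metrics operate on a :class:`WeightedGraph` — the binary topology of a
significant network carrying subject-specific lagged-coherence weights
``w_ij`` in [0, 1].

* Characteristic path length ``L_w``: edge lengths are ``1/w_ij`` (stronger
  coupling = shorter functional distance), ``d_ij^w`` is the weighted
  shortest path, and ``L_w`` is the mean of ``d_ij^w`` over ordered pairs
  ``i != j`` (sum divided by ``n (n-1)``).  Scaling all weights by ``c > 0``
  scales ``L_w`` by ``1/c``.
* Mean clustering coefficient ``C_w``: weights are first rescaled by the
  global maximum; the weighted geometric mean of triangles around node ``i``
  is ``t_i^w = 1/2 sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3)``, and
  ``C_i = 2 t_i^w / (k_i (k_i - 1))`` with ``k_i`` the binary degree
  (``C_i = 0`` for ``k_i < 2``); ``C_w`` is the mean of ``C_i`` over all
  nodes and lies in [0, 1].  The max-normalization makes ``C_w`` invariant
  to uniform weight scaling.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, shortest_path

logger = logging.getLogger(__name__)

#: Floor applied to zero weights sitting on significant topology, so the
#: component stays connected for path computation.
WEIGHT_FLOOR = 1e-6


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weights on a fixed binary topology (no self-loops)."""

    weights: np.ndarray    # (n, n) float, zero wherever topology is zero
    topology: np.ndarray   # (n, n) bool
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        w, a = np.asarray(self.weights, float), np.asarray(self.topology, bool)
        if w.shape != a.shape or w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights and topology must be equal square matrices")
        if np.any(a & np.eye(len(a), dtype=bool)):
            raise ValueError("self-loops are not allowed")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(w[~a] != 0):
            raise ValueError("weights must be zero off the topology")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        self.weights, self.topology = w, a

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def degree(self) -> np.ndarray:
        return self.topology.sum(axis=0).astype(int)

    @classmethod
    def from_adjacency(cls, topology: np.ndarray, weights: np.ndarray,
                       node_labels: list[str] | None = None,
                       floor: float = WEIGHT_FLOOR) -> "WeightedGraph":
        """Restrict a full weight matrix to a binary topology, flooring zero
        weights that sit on topology edges (loudly logged)."""
        a = np.asarray(topology, bool)
        w = np.where(a, np.asarray(weights, float), 0.0)
        w = 0.5 * (w + w.T)
        zero_on_edge = a & (w <= 0)
        if zero_on_edge.any():
            logger.warning("WeightedGraph: %d topology edge(s) with zero weight "
                           "floored at %g", int(zero_on_edge.sum()) // 2, floor)
            w[zero_on_edge] = floor
        return cls(weights=w, topology=a, node_labels=node_labels)


def _check_connected(topology: np.ndarray) -> None:
    n_comp, _ = connected_components(topology.astype(int), directed=False)
    if n_comp > 1:
        raise ValueError("graph is disconnected; pass a single component")


def char_path_length(g: WeightedGraph) -> float:
    """Weighted characteristic path length (mean shortest 1/w-length path)."""
    if g.n < 2:
        raise ValueError("need at least 2 nodes")
    _check_connected(g.topology)
    if np.any(g.topology & (g.weights <= 0)):
        raise ValueError("zero-weight edge inside topology; floor weights first")
    lengths = np.zeros_like(g.weights)
    lengths[g.topology] = 1.0 / g.weights[g.topology]
    d = shortest_path(lengths, method="D", directed=False, unweighted=False)
    n = g.n
    off = ~np.eye(n, dtype=bool)
    return float(d[off].sum() / (n * (n - 1)))


def clustering_coefficient(g: WeightedGraph,
                           normalization: str = "max") -> tuple[float, np.ndarray]:
    """Mean weighted clustering coefficient and the per-node vector.

    ``normalization="max"`` rescales weights by the graph maximum (the
    generic convention for unbounded weights; makes C_w invariant to uniform
    weight scaling).  ``normalization="unit"`` uses the weights as-is, which
    is appropriate for intrinsically [0, 1]-bounded weights such as lagged
    coherence and preserves overall coupling-level differences between
    graphs — the quantity a two-condition comparison is after.
    """
    if g.n < 1:
        raise ValueError("need at least 1 node")
    if normalization == "max":
        wmax = g.weights.max()
        w_hat = g.weights / wmax if wmax > 0 else g.weights
    elif normalization == "unit":
        if g.weights.max() > 1.0 + 1e-9:
            raise ValueError("unit normalization requires weights in [0, 1]")
        w_hat = g.weights
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    a = np.cbrt(w_hat)
    t = np.einsum("ij,jk,ki->i", a, a, a) / 2.0          # weighted triangles
    k = g.degree
    per_node = np.zeros(g.n)
    ok = k >= 2
    per_node[ok] = 2.0 * t[ok] / (k[ok] * (k[ok] - 1.0))
    return float(per_node.mean()), per_node


def metrics_per_subject(net, tensor, normalization: str = "unit") -> pd.DataFrame:
    """Per subject x condition graph metrics on a significant network.

    The binary topology comes from the network; the weights are each
    subject/condition lagged-coherence slice restricted to its edges (zero
    weights floored).  Because lagged coherence is already bounded in
    [0, 1], clustering uses unit normalization by default: a per-graph max
    rescaling would cancel exactly the between-condition coupling-level
    difference that the paired tests measure.  Returns the long-format
    paired table consumed by the statistical layer, with columns subject,
    condition, band, L_w, C_w.
    """
    if net.band is None or net.band not in tensor.bands:
        raise ValueError(f"network band {net.band!r} not present in tensor bands "
                         f"{tensor.bands}")
    nodes = net.nodes
    if nodes.size < 2:
        raise ValueError("network has fewer than 2 incident nodes")
    sub_top = net.adjacency[np.ix_(nodes, nodes)]
    band_vals = tensor.band_slice(net.band)
    rows = []
    for si, sub in enumerate(tensor.subjects):
        for ci, cond in enumerate(tensor.conditions):
            w_full = band_vals[si, ci][np.ix_(nodes, nodes)]
            g = WeightedGraph.from_adjacency(sub_top, w_full)
            lw = char_path_length(g)
            cw, _ = clustering_coefficient(g, normalization=normalization)
            rows.append({"subject": sub, "condition": cond, "band": net.band,
                         "contrast": net.contrast, "L_w": lw, "C_w": cw})
    return pd.DataFrame(rows)
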