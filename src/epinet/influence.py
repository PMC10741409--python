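"""Composite node-influence scoring: hubness, spreading, desynchronization.

Two composite scores rank the nodes of a significant network:

* ``spreading = (NC' + CR') * (BC' + CI')`` — the ability of a node to
  propagate activity, combining neighborhood connectivity, ClusterRank,
  betweenness centrality and collective influence;
* ``hubness = DC' + LH'`` — the local impact of a node, combining degree
  centrality and the local H-index.

Primed quantities are min-max rescaled to [1, 100] across nodes (a constant
vector maps to all 100, logged); each composite is itself rescaled to
[1, 100] afterwards, so the top hub scores exactly 100.

Component definitions (binary topology, ``k`` = degree, ``Γ(i)`` = neighbors):

* ``NC_i`` — mean degree of i's neighbors;
* ``CR_i = 10^(-c_i) * Σ_{j∈Γ(i)} (k_j + 1)`` with ``c_i`` the local
  clustering coefficient of i;
* ``BC_i`` — shortest-path betweenness;
* ``CI_i = (k_i - 1) * Σ_{j: dist(i,j)=ℓ} (k_j - 1)`` over the exact-ℓ shell
  (default ℓ = 2);
* ``DC_i = k_i``;
* ``LH_i = h(i) + Σ_{j∈Γ(i)} h(j)`` where ``h(j)`` is the H-index of the
  degrees of j's neighbors.

Group-level scores (the published-table analogue) are computed on the binary
topology of the detected network.  Subject-level score tables — the input to
the paired spreading-difference permutation test — use weighted counterparts
of the same six components (degree -> strength, betweenness on 1/w edge
lengths, weighted triangle clustering in the ClusterRank damping), since a
shared binary topology carries no between-subject or between-condition
variation; see docs/methods.md.
"""
from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components, shortest_path

from .graphmetrics import WeightedGraph, clustering_coefficient

logger = logging.getLogger(__name__)

COMPONENT_NAMES = ("NC", "CR", "BC", "CI", "DC", "LH")


# ---------------------------------------------------------------------------
# raw components

def _h_index(values: np.ndarray) -> int:
    """Largest integer h such that at least h entries are >= h."""
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    h = 0
    for rank, x in enumerate(v, start=1):
        if x >= rank:
            h = rank
        else:
            break
    return h


def _binary_checks(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency, dtype=bool)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 nodes")
    if not np.array_equal(a, a.T) or a.diagonal().any():
        raise ValueError("adjacency must be symmetric with zero diagonal")
    n_comp, _ = connected_components(a.astype(int), directed=False)
    if n_comp > 1:
        raise ValueError("graph must be connected")
    return a


def raw_components(adjacency: np.ndarray, shell: int = 2) -> pd.DataFrame:
    """The six raw influence components on a connected binary graph.

    Returns a DataFrame with columns NC, CR, BC, CI, DC, LH (one row per node).
    """
    if not 1 <= shell <= 3:
        raise ValueError("shell must be 1, 2 or 3")
    a = _binary_checks(adjacency)
    n = a.shape[0]
    af = a.astype(float)
    k = a.sum(axis=0).astype(float)

    nc = (af @ k) / k                                    # mean neighbor degree

    tri = np.einsum("ij,jk,ki->i", af, af, af) / 2.0
    c = np.zeros(n)
    many = k >= 2
    c[many] = 2.0 * tri[many] / (k[many] * (k[many] - 1.0))
    cr = 10.0 ** (-c) * (af @ (k + 1.0))

    g = nx.from_numpy_array(a)
    bc_dict = nx.betweenness_centrality(g, normalized=False)
    bc = np.array([bc_dict[i] for i in range(n)])

    dist = shortest_path(a.astype(int), method="D", directed=False, unweighted=True)
    shell_mask = dist == shell
    ci = (k - 1.0) * (shell_mask @ (k - 1.0))

    h = np.array([_h_index(k[a[j]]) for j in range(n)], dtype=float)
    lh = h + af @ h

    return pd.DataFrame({"NC": nc, "CR": cr, "BC": bc, "CI": ci, "DC": k, "LH": lh})


def weighted_raw_components(g: WeightedGraph, shell: int = 2) -> pd.DataFrame:
    """Weighted counterparts of the six components on a subject-level graph.

    Degree is replaced by strength ``s_i = Σ_j w_ij``; betweenness uses edge
    lengths ``1/w``; the ClusterRank damping exponent is the weighted
    (geometric-mean, max-normalized) clustering coefficient; collective
    influence drops the binary ``-1`` offsets; the H-index is taken over
    neighbor strengths.  Shells are still measured on the binary topology.
    """
    if not 1 <= shell <= 3:
        raise ValueError("shell must be 1, 2 or 3")
    a = g.topology
    n = g.n
    if n < 3:
        raise ValueError("need at least 3 nodes")
    af = a.astype(float)
    k = a.sum(axis=0).astype(float)
    s = g.weights.sum(axis=0)

    nc = (af @ s) / k

    _, c_w = clustering_coefficient(g)
    cr = 10.0 ** (-c_w) * (af @ (s + 1.0))

    gx = nx.from_numpy_array(np.where(a, 1.0 / np.where(g.weights > 0, g.weights, np.inf), 0.0))
    bc_dict = nx.betweenness_centrality(gx, normalized=False, weight="weight")
    bc = np.array([bc_dict[i] for i in range(n)])

    dist = shortest_path(a.astype(int), method="D", directed=False, unweighted=True)
    shell_mask = dist == shell
    ci = s * (shell_mask @ s)

    h = np.array([_h_index(s[a[j]]) for j in range(n)], dtype=float)
    lh = h + af @ h

    return pd.DataFrame({"NC": nc, "CR": cr, "BC": bc, "CI": ci, "DC": s, "LH": lh})


# ---------------------------------------------------------------------------
# composites and classification

def minmax_rescale(x: np.ndarray, lo: float = 1.0, hi: float = 100.0) -> np.ndarray:
    """Min-max rescale to [lo, hi]; a constant vector maps to all ``hi``."""
    x = np.asarray(x, dtype=float)
    span = x.max() - x.min()
    if span == 0:
        logger.info("minmax_rescale: constant vector mapped to all %g", hi)
        return np.full_like(x, hi)
    return lo + (hi - lo) * (x - x.min()) / span


def composite_scores(raw: pd.DataFrame) -> pd.DataFrame:
    """Spreading and hubness scores on the [1, 100] scale.

    Each raw component is rescaled to [1, 100]; the composites
    ``(NC' + CR') * (BC' + CI')`` and ``DC' + LH'`` are then themselves
    rescaled to [1, 100].
    """
    if len(raw) < 2:
        raise ValueError("need at least 2 nodes")
    prim = {c: minmax_rescale(raw[c].to_numpy()) for c in COMPONENT_NAMES}
    spreading = (prim["NC"] + prim["CR"]) * (prim["BC"] + prim["CI"])
    hubness = prim["DC"] + prim["LH"]
    return pd.DataFrame({"spreading": minmax_rescale(spreading),
                         "hubness": minmax_rescale(hubness)}, index=raw.index)


def classify_hubs(hubness: np.ndarray, normal: bool | None = None,
                  alpha: float = 0.05) -> tuple[np.ndarray, float, str]:
    """Hub set from the distribution-dependent threshold rule.

    Normally distributed hubness scores (Shapiro-Wilk p >= alpha, or
    ``normal=True``) use mean + 1 SD; otherwise median + IQR.  Returns
    (hub indices, threshold, branch name).
    """
    h = np.asarray(hubness, dtype=float)
    if h.size < 4:
        raise ValueError("need at least 4 nodes for the normality test")
    if np.ptp(h) == 0:
        logger.warning("classify_hubs: constant hubness vector, no hubs")
        return np.array([], dtype=int), float(h[0]), "degenerate"
    if normal is None:
        normal = bool(stats.shapiro(h).pvalue >= alpha)
    if normal:
        thr = float(h.mean() + h.std(ddof=1))
        branch = "mean+sd"
    else:
        q1, q3 = np.percentile(h, [25, 75])
        thr = float(np.median(h) + (q3 - q1))
        branch = "median+iqr"
    return np.flatnonzero(h > thr), thr, branch


# ---------------------------------------------------------------------------
# subject-level tables and the spreading permutation test

def group_score_table(net, shell: int = 2) -> pd.DataFrame:
    """Group-level composite scores on the binary topology of a network."""
    nodes = net.nodes
    sub = net.adjacency[np.ix_(nodes, nodes)]
    raw = raw_components(sub, shell=shell)
    scores = composite_scores(raw)
    out = pd.concat([raw, scores], axis=1)
    out.insert(0, "node", nodes)
    return out


def subject_score_tables(net, tensor, shell: int = 2) -> pd.DataFrame:
    """Per subject x condition composite scores on the network topology with
    subject-specific lagged-coherence weights."""
    nodes = net.nodes
    if nodes.size < 3:
        raise ValueError("network has fewer than 3 incident nodes")
    sub_top = net.adjacency[np.ix_(nodes, nodes)]
    band_vals = tensor.band_slice(net.band)
    rows = []
    for si, subj in enumerate(tensor.subjects):
        for ci, cond in enumerate(tensor.conditions):
            w = band_vals[si, ci][np.ix_(nodes, nodes)]
            g = WeightedGraph.from_adjacency(sub_top, w)
            scores = composite_scores(weighted_raw_components(g, shell=shell))
            for local, node in enumerate(nodes):
                rows.append({"subject": subj, "condition": cond, "node": int(node),
                             "spreading": scores["spreading"].iloc[local],
                             "hubness": scores["hubness"].iloc[local]})
    return pd.DataFrame(rows)


def spreading_difference(tables: pd.DataFrame, n_perm: int = 5000,
                         seed: int | None = None, alpha: float = 0.05,
                         score: str = "spreading") -> pd.DataFrame:
    """Paired permutation test on per-node spreading-score differences.

    The statistic is the median across subjects of the per-subject
    (pre - rest) score; the null swaps conditions within subjects (sign
    flips); p-values are two-sided with the +1 correction and
    Benjamini-Hochberg corrected across nodes.  Nodes with q < alpha are
    flagged as spreaders.
    """
    from statsmodels.stats.multitest import multipletests

    wide = tables.pivot_table(index="subject", columns=["condition", "node"],
                              values=score, sort=True)
    subjects = wide.index
    if len(subjects) < 3:
        raise ValueError("need >= 3 subjects")
    nodes = sorted(tables["node"].unique())
    pre = wide["pre"][nodes].to_numpy()
    rest = wide["rest"][nodes].to_numpy()
    d = pre - rest                                        # (n_subj, n_nodes)

    obs = np.median(d, axis=0)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, len(subjects))) * 2 - 1
    perm = np.median(signs[:, :, None] * d[None, :, :], axis=1)   # (n_perm, n_nodes)
    p = (1 + (np.abs(perm) >= np.abs(obs)[None, :]).sum(axis=0)) / (1 + n_perm)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"node": nodes, "median_diff": obs, "p": p, "q": q,
                         "spreader": q < alpha})


def desync_degree(tensor, net) -> pd.DataFrame:
    """Per-node degree of desynchronization for a decreased-connectivity net.

    The group-median drop in node strength (sum of network-edge weights) from
    rest to pre is min-max rescaled to [1, 100]; nodes above the mean + 1 SD
    of the rescaled values are labeled desynchronized.
    """
    if net.contrast != "rest>pre":
        raise ValueError("desynchronization degree applies to decreased-connectivity "
                         "(rest>pre) networks only")
    nodes = net.nodes
    band_vals = tensor.band_slice(net.band)               # (n_subj, 2, R, R)
    masked = band_vals * net.adjacency[None, None]
    strength = masked.sum(axis=-1)                        # (n_subj, 2, R)
    drop = np.median(strength[:, 1] - strength[:, 0], axis=0)[nodes]   # rest - pre
    scaled = minmax_rescale(drop) if np.ptp(drop) > 0 else np.full(drop.shape, 100.0)
    thr = scaled.mean() + scaled.std(ddof=1) if scaled.size > 1 else np.inf
    labels = scaled > thr
    return pd.DataFrame({"node": nodes, "strength_drop": drop,
                         "desync_degree": scaled, "desynchronized": labels})
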