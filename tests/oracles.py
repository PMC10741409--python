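"""Independent brute-force oracles used to validate the library.

Everything here is deliberately written from first principles (explicit DFT
sums, Floyd-Warshall relaxation, exhaustive path/triangle/shell enumeration,
full sign-pattern enumeration) and shares no code path with the package.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# spectral: direct DFT cross-spectrum + lagged coherence

def dft_cross_spectrum(segments: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Plain rectangular-window DFT cross-spectra averaged over segments.

    segments: list of (n_ch, n_t) arrays.  Returns (S, freqs_normalized) with
    S of shape (n_ch, n_ch, n_t//2+1); freqs are cycles/sample.
    """
    n_ch, n_t = segments[0].shape
    n_f = n_t // 2 + 1
    S = np.zeros((n_ch, n_ch, n_f), dtype=complex)
    for seg in segments:
        X = np.zeros((n_ch, n_f), dtype=complex)
        t = np.arange(n_t)
        for f in range(n_f):
            basis = np.exp(-2j * np.pi * f * t / n_t)
            for c in range(n_ch):
                X[c, f] = np.sum((seg[c] - seg[c].mean()) * basis)
        for i in range(n_ch):
            for j in range(n_ch):
                S[i, j] += X[i] * np.conj(X[j])
    S /= len(segments)
    freqs = np.arange(n_f) / n_t
    return S, freqs


def lagged_coherence_from_spectrum(S: np.ndarray, bins) -> np.ndarray:
    """Bin-averaged |Im S| / sqrt(Sxx Syy - Re S^2) from any cross-spectrum."""
    n_ch = S.shape[0]
    out = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(n_ch):
            if i == j:
                continue
            vals = []
            for b in bins:
                sxx = S[i, i, b].real
                syy = S[j, j, b].real
                den = sxx * syy - S[i, j, b].real ** 2
                vals.append(0.0 if den <= 1e-10 * sxx * syy
                            else abs(S[i, j, b].imag) / math.sqrt(den))
            out[i, j] = float(np.mean(vals))
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# graphs: Floyd-Warshall and exhaustive triangles

def floyd_warshall_lengths(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest 1/w path lengths by full relaxation."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def char_path_length_bruteforce(weights: np.ndarray) -> float:
    d = floyd_warshall_lengths(weights)
    n = weights.shape[0]
    total = sum(d[i, j] for i in range(n) for j in range(n) if i != j)
    return total / (n * (n - 1))


def clustering_bruteforce(weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean geometric-mean-triangle clustering with max-normalized weights."""
    n = weights.shape[0]
    wmax = weights.max()
    w = weights / wmax if wmax > 0 else weights
    k = (weights > 0).sum(axis=0)
    per_node = np.zeros(n)
    for i in range(n):
        if k[i] < 2:
            continue
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        t /= 2.0
        per_node[i] = 2.0 * t / (k[i] * (k[i] - 1))
    return float(per_node.mean()), per_node


# ---------------------------------------------------------------------------
# influence components, brute force

def _all_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """Every shortest s-t path, by breadth-limited exhaustive search."""
    n = adj.shape[0]
    # BFS distance first
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u, v] and v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for v in range(n):
            if adj[u, v] and dist.get(v) == len(path):
                extend(path + [v])

    extend([s])
    return paths


def betweenness_bruteforce(adj: np.ndarray) -> np.ndarray:
    """Unnormalized shortest-path betweenness via path enumeration."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                bc[v] += through / len(paths)
    return bc


def h_index_bruteforce(values) -> int:
    vals = sorted(values, reverse=True)
    h = 0
    for cand in range(len(vals), 0, -1):
        if sum(1 for v in vals if v >= cand) >= cand:
            h = cand
            break
    return h


def influence_components_bruteforce(adj: np.ndarray, shell: int = 2) -> dict[str, np.ndarray]:
    """All six raw influence components by literal definition."""
    n = adj.shape[0]
    k = adj.sum(axis=0).astype(float)
    neighbors = [set(np.flatnonzero(adj[i])) for i in range(n)]

    nc = np.array([np.mean([k[j] for j in neighbors[i]]) for i in range(n)])

    c = np.zeros(n)
    for i in range(n):
        if k[i] >= 2:
            links = sum(1 for j in neighbors[i] for h in neighbors[i]
                        if j < h and adj[j, h])
            c[i] = 2.0 * links / (k[i] * (k[i] - 1))
    cr = np.array([10.0 ** (-c[i]) * sum(k[j] + 1 for j in neighbors[i])
                   for i in range(n)])

    bc = betweenness_bruteforce(adj)

    # exact-shell ball expansion
    ci = np.zeros(n)
    for i in range(n):
        ball = {i: 0}
        frontier = {i}
        for depth in range(1, shell + 1):
            frontier = {v for u in frontier for v in neighbors[u] if v not in ball}
            for v in frontier:
                ball[v] = depth
        shell_nodes = [v for v, depth in ball.items() if depth == shell]
        ci[i] = (k[i] - 1) * sum(k[j] - 1 for j in shell_nodes)

    h = np.array([h_index_bruteforce([k[u] for u in neighbors[j]]) for j in range(n)],
                 dtype=float)
    lh = np.array([h[i] + sum(h[j] for j in neighbors[i]) for i in range(n)])

    return {"NC": nc, "CR": cr, "BC": bc, "CI": ci, "DC": k, "LH": lh}


# ---------------------------------------------------------------------------
# exact paired-permutation references

def exact_signflip_max_component_p(d: np.ndarray, threshold: float,
                                   n_rois: int, iu) -> float:
    """Exact NBS p for the largest observed component by enumerating all
    2^n sign patterns (one-sided contrast on the given differences)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = d.shape[0]

    def tvec(dd):
        mean = dd.mean(axis=0)
        sd = dd.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, mean / (sd / math.sqrt(n)),
                         np.where(mean != 0, np.sign(mean) * 1e6, 0.0))
        return t

    def max_comp(tv):
        supra = tv > threshold
        if not supra.any():
            return 0
        adj = np.zeros((n_rois, n_rois), dtype=bool)
        adj[iu[0][supra], iu[1][supra]] = True
        adj |= adj.T
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        counts = np.bincount(labels[iu[0][supra]], minlength=n_comp)
        return int(counts.max())

    obs = max_comp(tvec(d))
    count = 0
    total = 2 ** n
    for bits in range(total):
        signs = np.array([1 if bits >> s & 1 else -1 for s in range(n)])
        if max_comp(tvec(signs[:, None] * d)) >= obs:
            count += 1
    return count / total


def exact_signflip_median_p(d: np.ndarray) -> np.ndarray:
    """Exact two-sided sign-flip p for the median-difference statistic,
    enumerating all 2^n patterns; d is (n_subjects, n_nodes)."""
    n, m = d.shape
    obs = np.abs(np.median(d, axis=0))
    count = np.zeros(m)
    total = 2 ** n
    for bits in range(total):
        signs = np.array([1 if bits >> s & 1 else -1 for s in range(n)])
        stat = np.abs(np.median(signs[:, None] * d, axis=0))
        count += stat >= obs - 1e-12
    return count / total


def exact_wilcoxon_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns
    of the absolute values (no ties assumed, zeros removed)."""
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    count = 0
    for bits in range(2 ** n):
        w = sum(ranks[i] for i in range(n) if bits >> i & 1)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2 ** n
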