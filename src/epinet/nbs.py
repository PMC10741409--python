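"""Network-Based Statistics (NBS) for a one-group, paired two-condition design.

Edge-wise paired t statistics are thresholded at a component-forming value
``T``; the connected components of the supra-threshold graph are the
candidate networks, scored by extent (edge count).  The null distribution of
the maximum component extent is built by randomly swapping the two conditions
within each subject (sign flips of the per-subject difference vectors), which
controls the family-wise error rate over components for each one-sided
contrast.  Both contrasts (pre>rest and rest>pre) are evaluated.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

#: Sentinel t value for zero-variance, nonzero-mean edges (always supra-threshold).
T_SENTINEL = 1e6

CONTRASTS = ("pre>rest", "rest>pre")


@dataclass(frozen=True)
class SignificantNetwork:
    """One supra-threshold connected component and its permutation p-values."""

    adjacency: np.ndarray          # (n_rois, n_rois) bool, symmetric, zero diagonal
    contrast: str                  # "pre>rest" or "rest>pre"
    component_size: int            # edge count
    p_raw: float
    p_corrected: float | None = None
    band: str | None = None
    threshold: float = 1.5
    n_perm: int = 0

    @property
    def nodes(self) -> np.ndarray:
        """Indices of nodes incident to at least one component edge."""
        return np.flatnonzero(self.adjacency.any(axis=0))

    def edges(self) -> list[tuple[int, int]]:
        iu = np.triu_indices_from(self.adjacency, k=1)
        sel = self.adjacency[iu]
        return list(zip(iu[0][sel].tolist(), iu[1][sel].tolist()))

    def save(self, path: str | Path, roi_labels: list[str] | None = None) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "adjacency": self.adjacency.astype(int).tolist(),
            "contrast": self.contrast,
            "component_size": self.component_size,
            "p_raw": self.p_raw,
            "p_corrected": self.p_corrected,
            "band": self.band,
            "threshold": self.threshold,
            "n_perm": self.n_perm,
            "roi_labels": roi_labels,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SignificantNetwork":
        d = json.loads(Path(path).read_text())
        return cls(adjacency=np.asarray(d["adjacency"], dtype=bool),
                   contrast=d["contrast"], component_size=d["component_size"],
                   p_raw=d["p_raw"], p_corrected=d.get("p_corrected"),
                   band=d.get("band"), threshold=d.get("threshold", 1.5),
                   n_perm=d.get("n_perm", 0))


def _t_from_moments(mean: np.ndarray, ssq: np.ndarray, n: int) -> np.ndarray:
    """Vectorized one-sample t from the mean and raw sum of squares."""
    var = (ssq - n * mean ** 2) / (n - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0
    t = np.where(zero_sd, np.sign(mean) * T_SENTINEL, t)
    return t


def edge_paired_t(values: np.ndarray, contrast: str = "pre>rest") -> np.ndarray:
    """Edge-wise paired t matrix for one band slice.

    Parameters
    ----------
    values : (n_subjects, 2, n_rois, n_rois) array; axis 1 is (pre, rest)
    contrast : "pre>rest" tests the mean of pre-rest; "rest>pre" its negation

    Zero-variance edges get t = 0 when the mean difference is also zero, and
    the sentinel ``T_SENTINEL`` (capped, logged) when it is not.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 4 or values.shape[1] != 2:
        raise ValueError("values must have shape (n_subjects, 2, n_rois, n_rois)")
    n = values.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}")
    d = values[:, 0] - values[:, 1]
    if contrast == "rest>pre":
        d = -d
    mean = d.mean(axis=0)
    ssq = (d ** 2).sum(axis=0)
    t = _t_from_moments(mean, ssq, n)
    n_degen = int(np.count_nonzero(np.abs(t) >= T_SENTINEL) // 2)
    if n_degen:
        logger.warning("edge_paired_t: %d edge(s) with zero-variance nonzero-mean "
                       "differences capped at sentinel t", n_degen)
    np.fill_diagonal(t, 0.0)
    return t


def _max_component_extent(adj: np.ndarray) -> int:
    """Largest connected-component edge count of a boolean adjacency matrix."""
    if not adj.any():
        return 0
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    iu = np.triu_indices_from(adj, k=1)
    sel = adj[iu]
    counts = np.bincount(labels[iu[0][sel]], minlength=n_comp)
    return int(counts.max())


def _components(adj: np.ndarray) -> list[np.ndarray]:
    """Adjacency matrices of the connected components with >= 1 edge."""
    if not adj.any():
        return []
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    out = []
    for c in range(n_comp):
        in_c = labels == c
        sub = adj & in_c[:, None] & in_c[None, :]
        if sub.any():
            out.append(sub)
    return out


def nbs_test(values: np.ndarray, threshold: float = 1.5, n_perm: int = 5000,
             seed: int | None = None, contrasts: tuple[str, ...] = CONTRASTS,
             alpha: float | None = 0.05, band: str | None = None,
             ) -> list[SignificantNetwork]:
    """Run NBS on one band slice for the requested contrasts.

    Parameters
    ----------
    values : (n_subjects, 2, n_rois, n_rois), axis 1 = (pre, rest)
    threshold : component-forming t threshold (T > 0); edges enter the graph
        when their paired t exceeds it
    n_perm : number of within-subject condition-swap permutations (>= 100)
    alpha : report ceiling on the raw permutation p; ``None`` returns every
        component
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    values = np.asarray(values, dtype=float)
    if values.ndim != 4 or values.shape[1] != 2:
        raise ValueError("values must have shape (n_subjects, 2, n_rois, n_rois)")
    n_subj, _, n_rois, _ = values.shape
    if n_subj < 3:
        raise ValueError(f"need >= 3 subjects, got {n_subj}")

    iu = np.triu_indices(n_rois, k=1)
    d = values[:, 0] - values[:, 1]
    dvec = d[:, iu[0], iu[1]]                             # (n_subj, n_edges)
    ssq = (dvec ** 2).sum(axis=0)

    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n_subj)) * 2 - 1
    perm_mean = signs @ dvec / n_subj                     # (n_perm, n_edges)
    perm_t = _t_from_moments(perm_mean, ssq[None, :], n_subj)

    null_max = {c: np.zeros(n_perm, dtype=int) for c in contrasts}
    adj = np.zeros((n_rois, n_rois), dtype=bool)
    for p in range(n_perm):
        for contrast in contrasts:
            tvec = perm_t[p] if contrast == "pre>rest" else -perm_t[p]
            supra = tvec > threshold
            adj[:] = False
            adj[iu[0][supra], iu[1][supra]] = True
            adj |= adj.T
            null_max[contrast][p] = _max_component_extent(adj)

    results: list[SignificantNetwork] = []
    for contrast in contrasts:
        t_obs = edge_paired_t(values, contrast)
        supra = np.triu(t_obs > threshold, k=1)
        supra = supra | supra.T
        for comp in _components(supra):
            size = int(comp.sum()) // 2
            p_raw = (1 + int((null_max[contrast] >= size).sum())) / (1 + n_perm)
            if alpha is None or p_raw < alpha:
                results.append(SignificantNetwork(
                    adjacency=comp, contrast=contrast, component_size=size,
                    p_raw=p_raw, band=band, threshold=threshold, n_perm=n_perm))
    results.sort(key=lambda r: (r.p_raw, -r.component_size))
    return results


def correct_across_bands(results_by_band: dict[str, list[SignificantNetwork]],
                         method: str = "bonferroni",
                         ) -> dict[str, list[SignificantNetwork]]:
    """Attach across-band corrected p-values to every component.

    ``bonferroni`` multiplies each raw p by the number of bands tested
    (capped at 1); ``bh`` applies Benjamini-Hochberg across all components.
    """
    if not results_by_band:
        raise ValueError("need results for at least one band")
    n_bands = len(results_by_band)
    if method == "bonferroni":
        return {band: [replace(r, p_corrected=min(1.0, r.p_raw * n_bands)) for r in nets]
                for band, nets in results_by_band.items()}
    if method == "bh":
        from statsmodels.stats.multitest import multipletests
        flat = [(band, i, r) for band, nets in results_by_band.items()
                for i, r in enumerate(nets)]
        out = {band: list(nets) for band, nets in results_by_band.items()}
        if flat:
            q = multipletests([r.p_raw for _, _, r in flat], method="fdr_bh")[1]
            for (band, i, r), qi in zip(flat, q):
                out[band][i] = replace(r, p_corrected=float(qi))
        return out
    raise ValueError(f"unknown method {method!r}")
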