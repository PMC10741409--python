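"""Shared fixtures: small synthetic datasets and random-graph factories."""
from __future__ import annotations

import numpy as np
import pytest

from epinet import (GroundTruth, SimConfig, WeightedGraph, build_tensor,
                    generate_epoch_set, get_band)


def random_connected_graph(rng: np.random.Generator, n: int,
                           p: float = 0.5) -> np.ndarray:
    """Boolean adjacency of a connected Erdos-Renyi graph (rejection sampled,
    with a random spanning tree as fallback glue)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    for _ in range(50):
        a = rng.random((n, n)) < p
        a = np.triu(a, 1)
        a = a | a.T
        if connected_components(csr_matrix(a), directed=False)[0] == 1:
            return a
    # glue with a random spanning tree
    perm = rng.permutation(n)
    for i in range(1, n):
        a[perm[i], perm[rng.integers(0, i)]] = True
    a = a | a.T
    np.fill_diagonal(a, False)
    return a


def random_weighted_graph(rng: np.random.Generator, n: int,
                          p: float = 0.5) -> WeightedGraph:
    a = random_connected_graph(rng, n, p)
    w = np.where(a, rng.uniform(0.05, 1.0, (n, n)), 0.0)
    w = np.triu(w, 1)
    w = w + w.T
    return WeightedGraph(weights=w, topology=a)


@pytest.fixture(scope="session")
def small_sync_epochs():
    """Tiny planted-sync dataset shared by generator/connectivity tests."""
    cfg = SimConfig(n_subjects=6, n_rois=8, epochs_per_condition=2,
                    subject_cv=0.0, seed=11)
    truth = GroundTruth(sync_groups=((0, 1, 2),), desync_groups=(), hub_node=0)
    return cfg, truth, generate_epoch_set(cfg, truth)


@pytest.fixture(scope="session")
def small_sync_tensor(small_sync_epochs):
    cfg, truth, es = small_sync_epochs
    bands = (get_band("delta2"), get_band("alpha1"))
    return truth, build_tensor(es, bands=bands)
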