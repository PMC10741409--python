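"""Node-influence components, composite scores, hub/spreader classification."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epinet import (classify_hubs, composite_scores, desync_degree,
                    raw_components, spreading_difference)
from epinet.influence import minmax_rescale
from conftest import random_connected_graph
from oracles import exact_signflip_median_p, influence_components_bruteforce


def _star(n_leaves: int = 5) -> np.ndarray:
    n = n_leaves + 1
    a = np.zeros((n, n), dtype=bool)
    a[0, 1:] = a[1:, 0] = True
    return a


def _cycle(n: int = 5) -> np.ndarray:
    a = np.zeros((n, n), dtype=bool)
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = True
    return a


FIXED7 = np.zeros((7, 7), dtype=bool)
for i, j in [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (4, 5), (4, 6), (5, 6), (1, 3)]:
    FIXED7[i, j] = FIXED7[j, i] = True


class TestRawComponents:
    def test_star_center_dominates_degree_and_betweenness(self):
        raw = raw_components(_star(5))
        assert raw["DC"].idxmax() == 0 and raw["DC"][0] == 5
        assert raw["BC"].idxmax() == 0
        assert np.all(raw["BC"][1:] == 0)

    def test_cycle_is_vertex_transitive(self):
        raw = raw_components(_cycle(5))
        for col in raw.columns:
            assert raw[col].nunique() == 1

    def test_all_six_match_bruteforce_on_fixed_graph(self):
        raw = raw_components(FIXED7)
        oracle = influence_components_bruteforce(FIXED7)
        for name in ("NC", "CR", "BC", "CI", "DC", "LH"):
            assert np.allclose(raw[name].to_numpy(), oracle[name], atol=1e-8), name

    def test_all_six_match_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n = int(rng.integers(4, 12))
            adj = random_connected_graph(rng, n, p=0.45)
            raw = raw_components(adj)
            oracle = influence_components_bruteforce(adj)
            for name in ("NC", "CR", "BC", "CI", "DC", "LH"):
                assert np.allclose(raw[name].to_numpy(), oracle[name],
                                   atol=1e-8), name

    def test_shell_parameter_changes_collective_influence(self):
        raw1 = raw_components(FIXED7, shell=1)
        oracle1 = influence_components_bruteforce(FIXED7, shell=1)
        assert np.allclose(raw1["CI"].to_numpy(), oracle1["CI"], atol=1e-8)

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(11)
        adj = random_connected_graph(rng, 8)
        perm = rng.permutation(8)
        raw = raw_components(adj)
        raw_p = raw_components(adj[np.ix_(perm, perm)])
        for name in ("NC", "CR", "BC", "CI", "DC", "LH"):
            assert np.allclose(raw_p[name].to_numpy(),
                               raw[name].to_numpy()[perm], atol=1e-10)

    def test_small_or_disconnected_rejected(self):
        with pytest.raises(ValueError):
            raw_components(np.zeros((2, 2), dtype=bool))
        bad = np.zeros((4, 4), dtype=bool)
        bad[0, 1] = bad[1, 0] = bad[2, 3] = bad[3, 2] = True
        with pytest.raises(ValueError, match="connected"):
            raw_components(bad)


class TestCompositeScores:
    def test_star_center_hubness_is_100(self):
        scores = composite_scores(raw_components(_star(5)))
        assert scores["hubness"][0] == pytest.approx(100.0)
        assert np.all(scores["hubness"][1:] < 100)

    def test_vertex_transitive_graph_all_100(self):
        scores = composite_scores(raw_components(_cycle(6)))
        assert np.allclose(scores["hubness"], 100.0)
        assert np.allclose(scores["spreading"], 100.0)

    def test_hand_pipeline_on_fixed_graph(self):
        """rescale -> combine -> rescale, recomputed by hand from the raw table."""
        raw = raw_components(FIXED7)
        scores = composite_scores(raw)

        def rs(x):
            x = np.asarray(x, float)
            return (np.full_like(x, 100.0) if np.ptp(x) == 0
                    else 1 + 99 * (x - x.min()) / np.ptp(x))

        spread = rs((rs(raw["NC"]) + rs(raw["CR"])) * (rs(raw["BC"]) + rs(raw["CI"])))
        hub = rs(rs(raw["DC"]) + rs(raw["LH"]))
        assert np.allclose(scores["spreading"], spread, atol=1e-10)
        assert np.allclose(scores["hubness"], hub, atol=1e-10)

    def test_scores_live_in_1_100(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            adj = random_connected_graph(rng, int(rng.integers(4, 10)))
            scores = composite_scores(raw_components(adj))
            assert scores.to_numpy().min() >= 1.0 - 1e-9
            assert scores.to_numpy().max() <= 100.0 + 1e-9


class TestClassifyHubs:
    def test_forced_normal_branch_uses_mean_plus_sd(self):
        h = np.array([10.0, 20, 30, 40, 50])
        hubs, thr, branch = classify_hubs(h, normal=True)
        assert branch == "mean+sd"
        assert thr == pytest.approx(h.mean() + h.std(ddof=1))
        assert hubs.tolist() == [4]

    def test_forced_skewed_branch_uses_median_plus_iqr(self):
        h = np.array([10.0, 10, 10, 100])
        hubs, thr, branch = classify_hubs(h, normal=False)
        assert branch == "median+iqr"
        assert thr == pytest.approx(10 + (32.5 - 10.0))   # q3 = 32.5, q1 = 10
        assert hubs.tolist() == [3]

    def test_shapiro_gate_picks_skewed_branch_for_heavy_tail(self):
        rng = np.random.default_rng(13)
        h = np.concatenate([rng.normal(10, 0.5, 30), [200.0, 300.0]])
        _, _, branch = classify_hubs(h)
        assert branch == "median+iqr"

    def test_shapiro_gate_picks_normal_branch_for_bell_shape(self):
        rng = np.random.default_rng(14)
        h = rng.normal(50, 5, 40)
        _, _, branch = classify_hubs(h)
        assert branch == "mean+sd"

    def test_constant_vector_yields_no_hubs(self):
        hubs, _, branch = classify_hubs(np.full(6, 42.0))
        assert hubs.size == 0 and branch == "degenerate"

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            classify_hubs(np.array([1.0, 2.0, 3.0]))


class TestMinmaxRescale:
    def test_maps_to_1_100_and_constant_to_100(self):
        out = minmax_rescale(np.array([0.0, 5.0, 10.0]))
        assert out.tolist() == [1.0, 50.5, 100.0]
        assert np.all(minmax_rescale(np.full(4, 7.0)) == 100.0)


class TestSpreadingDifference:
    @staticmethod
    def _tables(d: np.ndarray, base: float = 50.0) -> pd.DataFrame:
        n_subj, n_nodes = d.shape
        rows = []
        for s in range(n_subj):
            for node in range(n_nodes):
                rows.append({"subject": f"s{s}", "condition": "pre",
                             "node": node, "spreading": base + d[s, node],
                             "hubness": 0.0})
                rows.append({"subject": f"s{s}", "condition": "rest",
                             "node": node, "spreading": base, "hubness": 0.0})
        return pd.DataFrame(rows)

    def test_identical_conditions_no_spreaders(self):
        tables = self._tables(np.zeros((6, 4)))
        out = spreading_difference(tables, n_perm=300, seed=0)
        assert np.all(out["p"] >= 0.99)
        assert not out["spreader"].any()

    def test_matches_exact_enumeration_for_five_subjects(self):
        rng = np.random.default_rng(15)
        d = rng.normal(0.4, 1.0, (5, 3))
        tables = self._tables(d)
        out = spreading_difference(tables, n_perm=4000, seed=1)
        p_exact = exact_signflip_median_p(d)
        assert np.allclose(out["p"].to_numpy(), p_exact, atol=0.05)

    def test_planted_shift_detected_with_fdr_control(self):
        # the sign-flip null of a *median* statistic has little power against
        # a same-sign homogeneous shift (flipped medians stay near +-c), so
        # the planted spreader carries a mixed-sign heterogeneous shift at a
        # sample size where the test is well powered
        rng = np.random.default_rng(0)
        d = rng.normal(0.0, 1.0, (30, 6))
        d[:, 2] += rng.normal(2.0, 1.5, 30)             # one true spreader
        out = spreading_difference(self._tables(d), n_perm=1000, seed=50)
        assert bool(out.loc[out["node"] == 2, "spreader"].iloc[0])
        assert out["spreader"].sum() <= 2

    def test_q_never_below_p(self):
        rng = np.random.default_rng(17)
        out = spreading_difference(self._tables(rng.normal(0, 1, (8, 5))),
                                   n_perm=500, seed=3)
        assert np.all(out["q"].to_numpy() >= out["p"].to_numpy() - 1e-12)


class TestDesyncDegree:
    @staticmethod
    def _net_and_tensor(drops: np.ndarray):
        """Tensor whose rest-minus-pre strength drop per node is `drops`."""
        from epinet import ConnectivityTensor, SignificantNetwork
        n = drops.size
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        rest = np.full((n, n), 0.5)
        np.fill_diagonal(rest, 0)
        values = np.zeros((4, 2, 1, n, n))
        pre = rest - np.add.outer(drops, drops) / 2 * (adj / np.maximum(
            adj.sum(1, keepdims=True), 1))
        # simpler: subtract drop/deg from each incident edge symmetric part
        pre = rest.copy()
        for i in range(n):
            for j in range(n):
                if adj[i, j]:
                    pre[i, j] -= (drops[i] + drops[j]) / (2 * 2)
        values[:, 0, 0] = pre
        values[:, 1, 0] = rest
        tensor = ConnectivityTensor(values=values,
                                    subjects=[f"s{k}" for k in range(4)],
                                    conditions=("pre", "rest"), bands=["alpha1"],
                                    roi_labels=[f"r{k}" for k in range(n)])
        net = SignificantNetwork(adjacency=adj, contrast="rest>pre",
                                 component_size=n - 1, p_raw=0.01, band="alpha1")
        return net, tensor

    def test_requires_decreased_connectivity_network(self):
        net, tensor = self._net_and_tensor(np.array([0.1, 0.2, 0.3, 0.1]))
        import dataclasses
        flipped = dataclasses.replace(net, contrast="pre>rest")
        with pytest.raises(ValueError, match="rest>pre"):
            desync_degree(tensor, flipped)

    def test_no_condition_difference_no_labels(self):
        net, tensor = self._net_and_tensor(np.zeros(5))
        out = desync_degree(tensor, net)
        assert np.all(out["strength_drop"] == 0)
        assert not out["desynchronized"].any()

    def test_max_drop_node_rescales_to_100(self):
        net, tensor = self._net_and_tensor(np.array([0.05, 0.1, 0.6, 0.05, 0.02]))
        out = desync_degree(tensor, net)
        top = out.loc[out["strength_drop"].idxmax()]
        assert top["desync_degree"] == pytest.approx(100.0)
        assert int(top["node"]) == 2

    def test_planted_desync_identifies_highest_strength_loss(self, ):
        """End-to-end: the planted alpha1 subnetwork's strongest-loss node
        attains the top desynchronization degree."""
        from epinet import (GroundTruth, SimConfig, SignificantNetwork,
                            build_tensor, generate_epoch_set, get_band)
        cfg = SimConfig(n_subjects=8, n_rois=8, epochs_per_condition=2, seed=31)
        truth = GroundTruth(sync_groups=((6, 7),), desync_groups=((0, 1, 2), (2, 3, 4)),
                            desync_gain=0.3, hub_node=6)
        tensor = build_tensor(generate_epoch_set(cfg, truth),
                              bands=(get_band("alpha1"),))
        adj = np.zeros((8, 8), dtype=bool)
        for i, j in truth.desync_edges:
            adj[i, j] = adj[j, i] = True
        net = SignificantNetwork(adjacency=adj, contrast="rest>pre",
                                 component_size=len(truth.desync_edges),
                                 p_raw=0.01, band="alpha1")
        out = desync_degree(tensor, net)
        top_node = int(out.loc[out["desync_degree"].idxmax(), "node"])
        assert top_node == 2   # shared node of both desync triangles
        assert out["desync_degree"].max() == pytest.approx(100.0)
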