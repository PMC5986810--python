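"""Graph-analysis core: signed Q, optimizers, thresholds, hubs."""

import numpy as np
import pandas as pd
import pytest
import networkx as nx
from hypothesis import given, settings
from hypothesis import strategies as st

from sadnet import (
    degree,
    detect_communities,
    exhaustive_best_partition,
    hub_permutation_check,
    identify_hubs,
    node_metrics,
    participation_coefficient,
    scan_gamma_neg,
    select_threshold,
    signed_modularity,
    threshold_matrix,
)
from sadnet.connectivity import ConnectivityMatrix
from sadnet.graph import _canonical


def _random_signed(rng, n):
    w = rng.uniform(-1, 1, (n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return w


class TestSignedModularity:
    def test_two_disconnected_cliques_give_half(self, two_cliques):
        w, planted = two_cliques
        assert signed_modularity(w, planted, 1.0, 1.0) == pytest.approx(0.5, abs=1e-12)

    def test_single_community_all_positive_is_zero(self, two_cliques):
        w, _ = two_cliques
        assert signed_modularity(w, np.zeros(6), 1.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_negative_inter_community_edge_does_not_enter(self, two_cliques):
        w, planted = two_cliques
        base = signed_modularity(w, planted, 1.0, 0.0)
        w2 = w.copy()
        w2[0, 3] = w2[3, 0] = -1.0
        # with gamma_neg = 0 the negative term reduces to within-community
        # negative weight, which this inter-community edge never contributes
        with_edge = signed_modularity(w2, planted, 1.0, 0.0)
        assert with_edge == pytest.approx(base, abs=1e-12)

    def test_matches_newman_girvan_on_nonnegative_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(5, 12))
            w = np.abs(_random_signed(rng, n))
            w[w < 0.4] = 0.0  # sparsify
            if w.sum() == 0:
                continue
            labels = rng.integers(0, 3, n)
            g = nx.from_numpy_array(w)
            comms = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
            reference = nx.community.modularity(g, comms, weight="weight")
            assert signed_modularity(w, labels, 1.0, 1.0) == pytest.approx(reference, abs=1e-10)

    def test_all_negative_matrix_fails(self):
        w = -np.ones((4, 4))
        np.fill_diagonal(w, 0.0)
        with pytest.raises(ValueError, match="v\\+"):
            signed_modularity(w, np.zeros(4))


class TestDetectCommunities:
    def test_planted_two_block_recovered_and_matches_oracle(self):
        rng = np.random.default_rng(3)
        w = np.where(
            (np.arange(8)[:, None] < 4) == (np.arange(8)[None, :] < 4), 0.5, -0.3
        ) + 0.02 * _random_signed(rng, 8)
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        oracle_labels, oracle_q = exhaustive_best_partition(w, 1.0, 0.45)
        res = detect_communities(w, 1.0, 0.45, n_restarts=20, seed=0)
        assert res.Q == pytest.approx(oracle_q, abs=1e-10)
        np.testing.assert_array_equal(_canonical(res.partition), np.array([0] * 4 + [1] * 4))

    def test_near_zero_matrix_is_handled(self, rng):
        w = 1e-6 * _random_signed(rng, 10)
        res = detect_communities(w, 1.0, 0.45, n_restarts=5, seed=0)
        assert abs(res.Q) < 1.0  # no failure, finite quality

    def test_node_permutation_equivariance(self, rng):
        w = _random_signed(rng, 9)
        perm = rng.permutation(9)
        res = detect_communities(w, 1.0, 0.6, n_restarts=30, seed=4)
        res_p = detect_communities(w[np.ix_(perm, perm)], 1.0, 0.6, n_restarts=30, seed=9)
        unpermuted = np.empty(9, dtype=int)
        unpermuted[perm] = res_p.partition
        assert res_p.Q == pytest.approx(res.Q, abs=1e-10)
        np.testing.assert_array_equal(_canonical(unpermuted), _canonical(res.partition))

    def test_candidate_partition_never_beaten_downward(self, rng):
        w = _random_signed(rng, 12)
        planted = np.array([0] * 6 + [1] * 6)
        res = detect_communities(w, 1.0, 0.45, n_restarts=1, seed=0, candidates=[planted])
        assert res.Q >= signed_modularity(w, planted, 1.0, 0.45) - 1e-10

    def test_deterministic_given_seed(self, rng):
        w = _random_signed(rng, 10)
        a = detect_communities(w, 1.0, 0.45, n_restarts=10, seed=3)
        b = detect_communities(w, 1.0, 0.45, n_restarts=10, seed=3)
        assert a.Q == b.Q
        np.testing.assert_array_equal(a.partition, b.partition)


class TestScanGammaNeg:
    def _mats(self, rng):
        w = np.where(
            (np.arange(8)[:, None] < 4) == (np.arange(8)[None, :] < 4), 0.5, -0.3
        ).astype(float)
        np.fill_diagonal(w, 0.0)
        return {"P1": w, "P2": w + 0.01 * _random_signed(rng, 8)}

    def test_single_grid_value_equals_two_detections(self, rng):
        mats = self._mats(rng)
        table = scan_gamma_neg(mats, [0.45], n_restarts=10, seed=0)
        assert len(table) == 1
        for p in mats:
            res = detect_communities(mats[p], 1.0, 0.45, n_restarts=10, seed=0)
            assert table.iloc[0][f"Q_{p}"] == pytest.approx(res.Q, abs=1e-12)

    def test_identical_paradigms_give_zero_contrast(self, rng):
        w = self._mats(rng)["P1"]
        table = scan_gamma_neg({"P1": w, "P2": w.copy()}, [0.3, 0.45, 0.6], n_restarts=10, seed=0)
        np.testing.assert_allclose(table["q_contrast"], 0.0, atol=1e-12)

    def test_anatomical_separation_flagged(self, rng):
        mats = self._mats(rng)
        grouping = np.array([0] * 4 + [1] * 4)
        table = scan_gamma_neg(mats, [0.45], n_restarts=10, seed=0, anatomical_grouping=grouping)
        assert bool(table.iloc[0]["separates_anatomical_P1"]) is True


class TestThreshold:
    def test_hand_computed_example(self):
        vals = np.array([[1.0, 0.8, 0.2], [0.8, 1.0, 0.1], [0.2, 0.1, 1.0]])
        mat = ConnectivityMatrix(vals, ["a", "b", "c"], "s", "p")
        adj = threshold_matrix(mat, 35.0)  # cutoff = 0.35 * 0.8 = 0.28
        np.testing.assert_array_equal(adj, [[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        np.testing.assert_array_equal(degree(adj), [1, 1, 0])

    def test_limits(self, rng):
        w = _random_signed(rng, 6)
        full = threshold_matrix(w, 1e-9)
        assert degree(full).sum() == 6 * 5
        top = threshold_matrix(w, 99.9999)
        assert degree(top).sum() == 2  # only the single strongest edge survives

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_degree_nonincreasing_in_threshold(self, seed):
        w = _random_signed(np.random.default_rng(seed), 7)
        degs = [degree(threshold_matrix(w, pct)) for pct in (10, 35, 60, 85)]
        for lower, higher in zip(degs, degs[1:]):
            assert np.all(higher <= lower)

    def test_all_zero_matrix_fails(self):
        with pytest.raises(ValueError, match="all-zero"):
            threshold_matrix(np.zeros((4, 4)), 35.0)


class TestDegreeAndParticipation:
    def test_degree_closed_forms(self):
        k4 = 1 - np.eye(4, dtype=int)
        np.testing.assert_array_equal(degree(k4), [3, 3, 3, 3])
        np.testing.assert_array_equal(degree(np.zeros((3, 3), dtype=int)), [0, 0, 0])
        star = np.zeros((5, 5), dtype=int)
        star[0, 1:] = star[1:, 0] = 1
        np.testing.assert_array_equal(degree(star), [4, 1, 1, 1, 1])

    def test_participation_closed_forms(self):
        # node 0: 4 edges all inside its own community -> P = 0
        adj = np.zeros((5, 5), dtype=int)
        adj[0, 1:] = adj[1:, 0] = 1
        part_same = np.zeros(5, dtype=int)
        assert participation_coefficient(adj, part_same)[0] == pytest.approx(0.0)
        # node 0: 2 edges in each of 2 communities -> P = 0.5
        part_split = np.array([0, 0, 0, 1, 1])
        assert participation_coefficient(adj, part_split)[0] == pytest.approx(0.5)
        # isolated node -> P = 0 by convention
        lonely = np.zeros((3, 3), dtype=int)
        np.testing.assert_allclose(participation_coefficient(lonely, np.array([0, 0, 1])), 0.0)

    def test_participation_bounded_by_community_count(self, rng):
        for _ in range(20):
            adj = (rng.random((8, 8)) < 0.5).astype(int)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            labels = rng.integers(0, 3, 8)
            m = len(np.unique(labels))
            p = participation_coefficient(adj, labels)
            assert np.all(p >= 0.0) and np.all(p <= 1 - 1 / m + 1e-12)


class TestSelectThreshold:
    def test_hand_built_spectrum_picks_separating_cutoff(self):
        # |w| levels 0.8 / 0.5 / 0.2: at 50% (cutoff 0.4) node 0 keeps 4 edges
        # and the rest 1, maximizing degree variance
        vals = np.full((5, 5), 0.2)
        vals[0, 1] = vals[1, 0] = 0.8
        for j in (2, 3, 4):
            vals[0, j] = vals[j, 0] = 0.5
        np.fill_diagonal(vals, 1.0)
        mat = ConnectivityMatrix(vals, [f"R{i}" for i in range(5)], "s", "p")
        best, table = select_threshold([mat], grid_pct=[25, 50, 75])
        assert best == 50.0
        assert set(table["threshold_pct"]) == {25.0, 50.0, 75.0}

    def test_flat_spectrum_warns_and_returns_smallest(self):
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 1.0)
        mat = ConnectivityMatrix(vals, list("abcd"), "s", "p")
        with pytest.warns(UserWarning, match="flat"):
            best, _ = select_threshold([mat], grid_pct=[20, 40, 60])
        assert best == 20.0

    def test_result_is_grid_member(self, rng):
        mats = [
            ConnectivityMatrix(
                np.clip(0.5 * (m + m.T) + np.eye(6) - np.diag(np.diag(0.5 * (m + m.T))), -1, 1),
                [f"R{i}" for i in range(6)],
                f"s{k}",
                "p",
            )
            for k, m in enumerate(rng.uniform(-0.8, 0.8, (3, 6, 6)))
        ]
        grid = [15, 35, 55, 75]
        best, _ = select_threshold(mats, grid_pct=grid)
        assert best in grid


class TestHubs:
    def _metrics(self, degrees, participations, n_subjects=3):
        rows = []
        for s in range(n_subjects):
            for i, (d, p) in enumerate(zip(degrees, participations)):
                rows.append(
                    {
                        "subject_id": f"s{s}",
                        "paradigm": "P",
                        "roi": f"R{i}",
                        "degree": d,
                        "participation": p,
                        "threshold_pct": 35.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_equal_degrees_give_no_hubs(self):
        metrics = self._metrics([4] * 6, [0.5] * 6)
        report = identify_hubs(metrics, paradigm="P", n_perm=100, seed=0)
        assert report.hubs == []

    def test_high_degree_node_flagged_iff_participation_above_mean(self):
        degrees = [10] + [4] * 19
        # across-node mean 4.3, SD (ddof=1) ~1.34 -> cutoff ~5.64 < 10
        hi_part = [0.6] + [0.4] * 19
        report = identify_hubs(self._metrics(degrees, hi_part), paradigm="P", n_perm=100, seed=0)
        assert report.hubs == ["R0"]
        assert report.network_degree_sd == pytest.approx(1.342, abs=0.01)
        lo_part = [0.2] + [0.4] * 19
        report2 = identify_hubs(self._metrics(degrees, lo_part), paradigm="P", n_perm=100, seed=0)
        assert report2.hubs == []

    def test_hub_rule_reproduces_inequality_on_report(self, default_spec, small_cohort_matrices):
        by_paradigm, _ = small_cohort_matrices
        mats = by_paradigm["Neutral-WM1"]
        metrics = node_metrics(mats, default_spec.planted_partition, 35.0)
        report = identify_hubs(metrics, paradigm="Neutral-WM1", n_perm=100, seed=0)
        cutoff = report.network_mean_degree + report.network_degree_sd
        for roi, mean_deg, mean_part, flagged in zip(
            report.roi_order, report.mean_degree, report.mean_participation, report.hub_flags
        ):
            expected = mean_deg > cutoff and mean_part > report.network_mean_participation
            assert flagged == expected, roi


class TestHubPermutation:
    def test_consistent_maximum_gets_minimal_p(self, rng):
        degrees = rng.integers(2, 8, size=(10, 6)).astype(float)
        degrees[:, 0] = 20.0  # always the maximum
        p = hub_permutation_check(degrees, n_perm=200, seed=0)
        assert p[0] == pytest.approx(1 / 201)

    def test_same_seed_identical(self, rng):
        degrees = rng.integers(0, 10, size=(8, 5)).astype(float)
        a = hub_permutation_check(degrees, n_perm=150, seed=7)
        b = hub_permutation_check(degrees, n_perm=150, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_exchangeable_nodes_give_roughly_uniform_p(self):
        rng = np.random.default_rng(11)
        small = 0
        total = 0
        for rep in range(40):
            degrees = rng.permuted(
                np.tile(np.arange(8, dtype=float), (12, 1)), axis=1
            )
            p = hub_permutation_check(degrees, n_perm=100, seed=rep)
            small += int(np.sum(p <= 0.05))
            total += p.size
        assert 0.0 <= small / total <= 0.12
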