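"""Recurrence plots, source/sink profiles, cycles, occupancy, surrogates."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import tmapper as tm
from tmapper.analytics import (
    CycleSet,
    dfc_recurrence,
    enumerate_cycles,
    geodesic_matrix,
    recurrence_l2,
    recurrence_matrix,
    source_sink_profiles,
)
from tmapper.network import TransitionNetwork
from tmapper.timeseries import MultivariateTimeSeries


def _net_from_edges(edges, members):
    g = nx.DiGraph()
    g.add_nodes_from(members.keys())
    g.add_edges_from(edges)
    n = sum(len(m) for m in members.values())
    return TransitionNetwork(graph=g, members=members, n_samples=n)


@pytest.fixture
def five_block_net():
    # ring 0->1->2->3->4->0 with a chord 1->3
    members = {i: [2 * i, 2 * i + 1] for i in range(5)}
    return _net_from_edges(
        [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0), (1, 3)], members
    )


class TestGeodesicMatrix:
    def test_zero_diagonal_and_two_cycle(self):
        net = _net_from_edges([(0, 1), (1, 0)], {0: [0], 1: [1]})
        D = geodesic_matrix(net)
        assert D[0, 0] == 0 and D[1, 1] == 0
        assert D[0, 1] == 1 and D[1, 0] == 1

    def test_matches_floyd_warshall(self, rng):
        for _ in range(5):
            g = nx.fast_gnp_random_graph(10, 0.35, directed=True,
                                         seed=int(rng.integers(1e6)))
            if not nx.is_strongly_connected(g):
                continue
            D = geodesic_matrix(g)
            n = 10
            F = np.full((n, n), np.inf)
            np.fill_diagonal(F, 0)
            for u, v in g.edges:
                F[u, v] = 1
            for m in range(n):
                for i in range(n):
                    for j in range(n):
                        F[i, j] = min(F[i, j], F[i, m] + F[m, j])
            np.testing.assert_array_equal(D, F)

    def test_unreachable_pair_raises_without_cap(self):
        g = nx.DiGraph([(0, 1)])
        with pytest.raises(ValueError, match="not strongly connected"):
            geodesic_matrix(g)
        D = geodesic_matrix(g, cap=9.0)
        assert D[1, 0] == 9.0


class TestRecurrenceMatrix:
    def test_same_block_zero_both_ways(self, five_block_net):
        R = recurrence_matrix(five_block_net, mode="network").R
        assert R[0, 1] == 0 and R[1, 0] == 0  # indices 0,1 share block 0

    def test_state_mode_equals_pairwise_distances(self, rng):
        X = rng.random((15, 3))
        ts = MultivariateTimeSeries(X=X, times=np.arange(15.0))
        R = recurrence_matrix(ts, mode="state").R
        np.testing.assert_allclose(R, tm.pairwise_distances(X))

    def test_five_block_hand_lookup(self, five_block_net):
        R = recurrence_matrix(five_block_net, mode="network").R
        G = geodesic_matrix(five_block_net)
        for t1 in range(10):
            for t2 in range(10):
                assert R[t1, t2] == G[t1 // 2, t2 // 2]


class TestDfcRecurrence:
    def test_stationary_correlation_structure_gives_small_distances(self, rng):
        # channels share one latent factor; window correlations are stable
        z = rng.standard_normal(400)
        X = np.column_stack([z + 0.05 * rng.standard_normal(400) for _ in range(4)])
        ts = MultivariateTimeSeries(X=X, times=np.arange(400.0))
        R = dfc_recurrence(ts, window=30)
        off = R.R[np.triu_indices_from(R.R, 1)]
        assert np.median(off) < 1.0  # Fisher-z units; near-identical windows

    def test_matches_brute_force_three_channels(self, rng):
        X = rng.standard_normal((40, 3))
        ts = MultivariateTimeSeries(X=X, times=np.arange(40.0))
        R = dfc_recurrence(ts, window=10)
        starts = range(0, 31)
        vecs = []
        for s in starts:
            C = np.corrcoef(X[s : s + 10], rowvar=False)
            v = [C[1, 0], C[2, 0], C[2, 1]]
            vecs.append(np.arctanh(np.clip(v, -1 + 1e-12, 1 - 1e-12)))
        vecs = np.array(vecs)
        expect = np.sqrt(((vecs[:, None, :] - vecs[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(R.R, expect, atol=1e-10)

    def test_zero_variance_channel_warns_and_zeroes(self, rng, caplog):
        X = rng.standard_normal((50, 3))
        X[:, 2] = 1.0
        ts = MultivariateTimeSeries(X=X, times=np.arange(50.0))
        with caplog.at_level("WARNING"):
            R = dfc_recurrence(ts, window=20)
        assert "zero-variance" in caplog.text
        assert np.all(np.isfinite(R.R))

    def test_requires_enough_samples_and_channels(self):
        ts = MultivariateTimeSeries(X=np.zeros((10, 1)), times=np.arange(10.0))
        with pytest.raises(ValueError):
            dfc_recurrence(ts, window=5)
        ts2 = MultivariateTimeSeries(X=np.zeros((10, 3)), times=np.arange(10.0))
        with pytest.raises(ValueError):
            dfc_recurrence(ts2, window=30)


class TestSourceSink:
    def test_symmetric_matrix_has_zero_difference(self, rng):
        A = rng.random((8, 8))
        R = A + A.T
        np.fill_diagonal(R, 0)
        _, _, diff = source_sink_profiles(R)
        np.testing.assert_allclose(diff, 0.0, atol=1e-12)

    def test_hand_computed_profiles(self):
        R = np.array([[0.0, 1.0, 2.0], [3.0, 0.0, 4.0], [5.0, 6.0, 0.0]])
        source, sink, diff = source_sink_profiles(R)
        np.testing.assert_allclose(source, [1.5, 3.5, 5.5])
        np.testing.assert_allclose(sink, [4.0, 3.5, 3.0])
        np.testing.assert_allclose(diff, [2.5, 0.0, -2.5])

    def test_normalization_by_maximum(self):
        R = np.array([[0.0, 2.0], [4.0, 0.0]])
        source, sink, _ = source_sink_profiles(R, normalize=True)
        np.testing.assert_allclose(source, [0.5, 1.0])

    def test_difference_sums_to_zero(self, rng):
        R = rng.random((12, 12))
        np.fill_diagonal(R, 0)
        _, _, diff = source_sink_profiles(R)
        assert diff.sum() == pytest.approx(0.0, abs=1e-10)


def _validate_cycle(graph, cyc):
    """Independent simple-closed-cycle check."""
    if len(set(cyc)) != len(cyc):
        return False
    edges = list(zip(cyc, list(cyc[1:]) + [cyc[0]]))
    return all(graph.has_edge(u, v) for u, v in edges)


class TestCycles:
    def test_directed_triangle(self):
        g = nx.DiGraph([(0, 1), (1, 2), (2, 0)])
        cs = enumerate_cycles(g)
        assert len(cs) == 1
        assert cs.lengths[0] == 3
        assert cs.cycles[0][0] == 0  # canonical start at smallest node

    def test_acyclic_chain_is_empty(self):
        g = nx.DiGraph([(0, 1), (1, 2), (2, 3)])
        assert len(enumerate_cycles(g)) == 0

    def test_random_digraph_cycles_are_valid_and_subset(self, rng):
        g = nx.fast_gnp_random_graph(12, 0.25, directed=True, seed=7)
        cs = enumerate_cycles(g)
        assert len(cs) > 0
        exhaustive = {
            tuple(c[c.index(min(c)) :] + c[: c.index(min(c))])
            for c in nx.simple_cycles(g)
        }
        for cyc in cs.cycles:
            assert _validate_cycle(g, cyc)
            assert cyc in exhaustive
        # rotations deduplicated
        assert len(set(cs.cycles)) == len(cs.cycles)


@pytest.fixture
def labeled_net():
    # 6 nodes; node 0 has highest degree; labels planted per node
    members = {0: [0, 1, 2, 3], 1: [4, 5], 2: [6, 7], 3: [8], 4: [9], 5: [10, 11]}
    edges = [(0, 1), (1, 0), (0, 2), (2, 0), (0, 3), (3, 4), (4, 0), (5, 0)]
    net = _net_from_edges(edges, members)
    labels = np.array(
        ["m", "m", "m", "a", "m", "a", "r", "r", "r", "v", "v", "v"]
    )
    return net, labels


class TestOccupancy:
    def test_single_label_gives_fraction_one(self, five_block_net):
        labels = np.array(["x"] * 10)
        occ = tm.degree_occupancy(five_block_net, labels, top_percent=40)
        assert occ.to_dict() == {"x": 1.0}

    def test_hand_planted_concentration(self, labeled_net):
        net, labels = labeled_net
        # top 1 node of 6 at ~17%: node 0 (degree 7)
        occ = tm.degree_occupancy(net, labels, top_percent=17)
        assert occ["m"] == pytest.approx(0.75)
        assert occ["a"] == pytest.approx(0.25)

    def test_fractions_sum_to_one(self, labeled_net):
        net, labels = labeled_net
        occ = tm.degree_occupancy(net, labels, top_percent=50)
        assert occ.sum() == pytest.approx(1.0)

    def test_tiny_percent_errors(self, labeled_net):
        net, labels = labeled_net
        with pytest.raises(ValueError, match="selects no node"):
            tm.degree_occupancy(net, labels, top_percent=0.1)

    def test_cycle_occupancy_excludes_top_nodes(self, labeled_net):
        net, labels = labeled_net
        table = tm.cycle_occupancy(net, labels, top_percent=17)
        # cycles through node 0: (0,1) len 2, (0,2) len 2, (0,3,4) len 3;
        # top node 0's own members are excluded from the tallies
        assert 2 in table.index and 3 in table.index
        row2 = table.loc[2]
        assert row2.sum() == pytest.approx(1.0)
        # length-2 cycles contribute members of nodes 1 and 2: m, a, r, r
        assert row2["r"] == pytest.approx(0.5)
        row3 = table.loc[3]  # nodes 3 (r) and 4 (v)
        assert row3["r"] == pytest.approx(0.5)
        assert row3["v"] == pytest.approx(0.5)

    def test_no_cycles_gives_empty_table(self):
        net = _net_from_edges([(0, 1)], {0: [0], 1: [1]})
        table = tm.cycle_occupancy(net, np.array(["x", "y"]), top_percent=50)
        assert isinstance(table, pd.DataFrame)
        assert table.empty


class TestRecurrenceL2:
    def test_identical_is_zero_and_symmetric(self, rng):
        A, B = rng.random((6, 6)), rng.random((6, 6))
        assert recurrence_l2(A, A) == 0.0
        assert recurrence_l2(A, B) == pytest.approx(recurrence_l2(B, A))

    def test_hand_value(self):
        A = np.array([[0.0, 1.0], [2.0, 0.0]])
        B = np.array([[0.0, 1.0], [0.0, 0.0]])
        assert recurrence_l2(A, B) == pytest.approx(2.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            recurrence_l2(np.zeros((2, 2)), np.zeros((3, 3)))


class TestNullModels:
    @pytest.fixture
    def ts(self, rng):
        return MultivariateTimeSeries(
            X=rng.standard_normal((64, 3)),
            times=np.arange(64.0),
            epochs=np.array([0] * 32 + [1] * 32),
        )

    def test_permutation_preserves_row_multiset(self, ts):
        sur = tm.null_models(ts, "permute", 1, seed=0)[0]
        a = np.sort(ts.X.round(12).view("f8").reshape(64, -1), axis=0)
        b = np.sort(sur.X.round(12).view("f8").reshape(64, -1), axis=0)
        np.testing.assert_array_equal(np.sort(ts.X, axis=0), np.sort(sur.X, axis=0))
        # rows move as units: every surrogate row appears in the original
        orig = {tuple(r) for r in ts.X}
        assert all(tuple(r) in orig for r in sur.X)

    def test_permutation_respects_epochs(self, ts):
        sur = tm.null_models(ts, "permute", 1, seed=1)[0]
        first = {tuple(r) for r in ts.X[:32]}
        assert all(tuple(r) in first for r in sur.X[:32])

    def test_phase_randomization_preserves_amplitude_spectrum(self, ts):
        sur = tm.null_models(ts, "phase_randomize", 1, seed=2)[0]
        for sl in ts.epoch_slices():
            for c in range(3):
                np.testing.assert_allclose(
                    np.abs(np.fft.rfft(sur.X[sl, c])),
                    np.abs(np.fft.rfft(ts.X[sl, c])),
                    atol=1e-9,
                )

    def test_seeded_determinism(self, ts):
        a = tm.null_models(ts, "permute", 3, seed=5)
        b = tm.null_models(ts, "permute", 3, seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.X, y.X)


def test_symbolic_agreement_perfect_and_mixed():
    members = {0: [0, 1, 2], 1: [3, 4, 5]}
    net = _net_from_edges([(0, 1), (1, 0)], members)
    assert tm.symbolic_agreement(net, np.array([7, 7, 7, 9, 9, 9])) == 1.0
    assert tm.symbolic_agreement(net, np.array([7, 7, 9, 9, 9, 9])) == pytest.approx(5 / 6)


def test_source_sink_regimes_on_toy_fixture(toy_fixture, toy_reconstruction):
    """During persistent single-attractor segments the occupied node is more
    source-like (sink distance exceeds source distance); the reverse holds
    around transition-dense segments."""
    ts, truth, sym = toy_fixture
    R = recurrence_matrix(toy_reconstruction, mode="network")
    source, sink, diff = source_sink_profiles(R)
    # transitions at known analytic times; mid-dwell samples are persistent
    trans = np.flatnonzero(np.diff(sym.symbols) != 0)
    persistent = np.ones(len(sym.symbols), dtype=bool)
    for t in trans:
        lo, hi = max(0, t - 30), min(len(persistent), t + 31)
        persistent[lo:hi] = False
    assert np.mean(diff[persistent]) > np.mean(diff[~persistent])
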