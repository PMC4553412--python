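"""Efficiency metrics, thresholding, null models, AUC summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tremornet as tn
from tremornet.graph_metrics import BinaryGraph, NullEnsemble, profiles_to_frame
from tremornet.wavelet_fc import ConnectivityMatrix


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return BinaryGraph(a)


def complete(n):
    a = np.ones((n, n), dtype=bool)
    np.fill_diagonal(a, False)
    return BinaryGraph(a)


def floyd_warshall_inv_mean(adj):
    """Brute-force all-pairs-shortest-path oracle (independent of the BFS path)."""
    n = len(adj)
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    return inv


class TestClosedForms:
    def test_complete_graph_efficiencies_are_one(self):
        g = complete(4)
        assert tn.global_efficiency(g) == 1.0
        assert tn.local_efficiency(g) == 1.0

    def test_empty_graph_efficiencies_are_zero(self):
        g = BinaryGraph(np.zeros((4, 4), dtype=bool))
        assert tn.global_efficiency(g) == 0.0
        assert tn.local_efficiency(g) == 0.0

    def test_path_of_three_nodes(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        assert tn.global_efficiency(g) == pytest.approx(5 / 6, abs=1e-12)

    def test_triangle_local_efficiency_is_one(self):
        assert tn.local_efficiency(complete(3)) == 1.0

    def test_star_graph(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])  # node 0 is the hub
        assert tn.local_efficiency(g) == 0.0
        e = tn.nodal_efficiency(g)
        assert e[0] == pytest.approx(1.0, abs=1e-12)
        assert e[1] == pytest.approx(2 / 3, abs=1e-12)

    def test_isolated_node_has_zero_nodal_efficiency(self):
        g = graph_from_edges(3, [(0, 1)])
        assert tn.nodal_efficiency(g)[2] == 0.0

    def test_single_node_rejected(self):
        g = BinaryGraph(np.zeros((1, 1), dtype=bool))
        for fn in (tn.global_efficiency, tn.local_efficiency, tn.nodal_efficiency):
            with pytest.raises(ValueError):
                fn(g)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_small_graphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            a = np.triu(rng.random((n, n)) < rng.uniform(0.1, 0.9), 1)
            a = a | a.T
            g = BinaryGraph(a)
            inv = floyd_warshall_inv_mean(a)
            assert tn.global_efficiency(g) == pytest.approx(
                inv.sum() / (n * (n - 1)), abs=1e-12
            )
            np.testing.assert_allclose(
                tn.nodal_efficiency(g), inv.sum(axis=1) / (n - 1), atol=1e-12
            )
            # local efficiency: brute-force over neighbor subgraphs
            expected = 0.0
            for i in range(n):
                nb = np.flatnonzero(a[i])
                k = len(nb)
                if k >= 2:
                    sub = a[np.ix_(nb, nb)]
                    expected += floyd_warshall_inv_mean(sub).sum() / (k * (k - 1))
            assert tn.local_efficiency(g) == pytest.approx(expected / n, abs=1e-12)

    def test_nodal_mean_equals_global_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            a = np.triu(rng.random((n, n)) < 0.2, 1)
            a = a | a.T
            g = BinaryGraph(a)
            assert tn.nodal_efficiency(g).mean() == pytest.approx(
                tn.global_efficiency(g), abs=1e-12
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**9))
    def test_adding_an_edge_never_decreases_global_efficiency(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        a = np.triu(rng.random((n, n)) < 0.3, 1)
        a = a | a.T
        missing = np.argwhere(np.triu(~a, 1))
        if len(missing) == 0:
            return
        i, j = missing[rng.integers(len(missing))]
        before = tn.global_efficiency(BinaryGraph(a))
        a[i, j] = a[j, i] = True
        assert tn.global_efficiency(BinaryGraph(a)) >= before - 1e-12


class TestThresholding:
    def test_top_k_edges_selected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.9
        w[2, 3] = w[3, 2] = 0.8
        w[0, 2] = w[2, 0] = 0.1
        g = tn.threshold_by_sparsity(w, 2 / 6)
        assert g.n_edges == 2
        assert g.adjacency[0, 1] and g.adjacency[2, 3] and not g.adjacency[0, 2]

    def test_grid_has_twenty_points(self):
        grid = tn.default_sparsity_grid()
        assert len(grid) == 20
        assert grid[0] == 0.02 and grid[-1] == 0.40

    def test_sparsity_within_one_edge_of_target(self, rng):
        w = rng.random((30, 30))
        w = (w + w.T) / 2
        for s in (0.05, 0.2, 0.4):
            g = tn.threshold_by_sparsity(w, s)
            assert abs(g.n_edges - s * 30 * 29 / 2) <= 1

    def test_ties_break_deterministically_by_index(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0.0)
        g = tn.threshold_by_sparsity(w, 2 / 6)
        # stable order over the upper triangle: (0,1) then (0,2)
        assert g.adjacency[0, 1] and g.adjacency[0, 2]
        assert g.n_edges == 2

    def test_nan_entries_never_selected(self):
        w = np.full((4, 4), np.nan)
        w[0, 1] = w[1, 0] = 0.2
        with pytest.warns(UserWarning, match="finite"):
            g = tn.threshold_by_sparsity(w, 0.5)
        assert g.n_edges == 1

    def test_near_complete_cap(self, rng):
        w = rng.random((6, 6))
        w = (w + w.T) / 2
        g = tn.threshold_by_sparsity(w, 0.999)
        assert g.n_edges == 15


class TestNullModels:
    def test_degree_sequence_always_preserved(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 40))
            a = np.triu(rng.random((n, n)) < 0.3, 1)
            a = a | a.T
            g = BinaryGraph(a)
            if g.n_edges < 2:
                continue
            null = tn.rewire_preserving_degree(g, seed=int(rng.integers(2**31 - 1)))
            np.testing.assert_array_equal(null.degrees(), g.degrees())
            assert not null.adjacency.diagonal().any()

    def test_complete_graph_is_rigid_under_swaps(self):
        g = complete(4)
        with pytest.warns(UserWarning, match="unchanged"):
            null = tn.rewire_preserving_degree(g, seed=3)
        np.testing.assert_array_equal(null.adjacency, g.adjacency)

    def test_different_seeds_give_different_rewirings(self, rng):
        a = np.triu(rng.random((60, 60)) < 0.3, 1)
        a = a | a.T
        g = BinaryGraph(a)
        n1 = tn.rewire_preserving_degree(g, seed=1)
        n2 = tn.rewire_preserving_degree(g, seed=2)
        assert not np.array_equal(n1.adjacency, n2.adjacency)
        np.testing.assert_array_equal(n1.degrees(), n2.degrees())

    def test_same_seed_reproduces_rewiring(self, rng):
        a = np.triu(rng.random((30, 30)) < 0.3, 1)
        a = a | a.T
        g = BinaryGraph(a)
        np.testing.assert_array_equal(
            tn.rewire_preserving_degree(g, seed=5).adjacency,
            tn.rewire_preserving_degree(g, seed=5).adjacency,
        )

    def test_ensemble_size_and_trivial_normalization(self, rng):
        a = np.triu(rng.random((30, 30)) < 0.3, 1)
        a = a | a.T
        g = BinaryGraph(a)
        ens = tn.build_null_ensemble(g, n_null=10, seed=0)
        assert ens.n_null == 10
        same = NullEnsemble(e_glob=np.full(5, 0.4), e_loc=np.full(5, 0.6), seed=0)
        assert tn.normalize_against_null(0.4, 0.6, same) == (1.0, 1.0)

    def test_er_graph_normalizes_to_one(self, rng):
        a = np.triu(rng.random((100, 100)) < 0.1, 1)
        a = a | a.T
        g = BinaryGraph(a)
        ens = tn.build_null_ensemble(g, n_null=20, seed=4)
        ng, nl = tn.normalize_against_null(
            tn.global_efficiency(g), tn.local_efficiency(g), ens
        )
        assert ng == pytest.approx(1.0, abs=0.05)
        assert nl == pytest.approx(1.0, abs=0.35)  # E_loc of sparse ER is noisy

    def test_ring_lattice_is_small_world_like(self):
        # ring lattice, 4 neighbors per side: high clustering, so normalized
        # local efficiency must exceed 1 against degree-matched nulls
        n, k = 100, 4
        a = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for d in range(1, k + 1):
                a[i, (i + d) % n] = a[(i + d) % n, i] = True
        g = BinaryGraph(a)
        ens = tn.build_null_ensemble(g, n_null=20, seed=9)
        ng, nl = tn.normalize_against_null(
            tn.global_efficiency(g), tn.local_efficiency(g), ens
        )
        assert nl > 1.0


class TestSmallWorldRule:
    @pytest.mark.parametrize(
        "nl,ng,expected",
        [(1.5, 1.0, True), (0.9, 1.0, False), (1.5, 1.25, False), (1.01, 0.91, True)],
    )
    def test_rule_application(self, nl, ng, expected):
        assert tn.is_small_world(nl, ng, tol=0.1) is expected

    def test_non_finite_inputs_are_not_small_world(self):
        assert tn.is_small_world(float("nan"), 1.0) is False


class TestAuc:
    def test_constant_curve_closed_form(self):
        grid = tn.default_sparsity_grid()
        assert tn.auc_over_sparsity(np.ones(20), grid) == pytest.approx(0.38, abs=1e-12)

    def test_zero_curve(self):
        grid = tn.default_sparsity_grid()
        assert tn.auc_over_sparsity(np.zeros(20), grid) == 0.0

    def test_linear_ramp_closed_form(self):
        grid = tn.default_sparsity_grid()
        ramp = np.linspace(0, 1, 20)
        assert tn.auc_over_sparsity(ramp, grid) == pytest.approx(0.19, abs=1e-12)

    def test_nan_values_rejected_with_thresholds_named(self):
        grid = tn.default_sparsity_grid()
        vals = np.ones(20)
        vals[3] = np.nan
        with pytest.raises(ValueError, match="0.08"):
            tn.auc_over_sparsity(vals, grid)


def test_efficiency_profile_assembles_curves_and_aucs(rng):
    w = rng.random((40, 40))
    w = (w + w.T) / 2
    cm = ConnectivityMatrix("s0", w - np.diag(np.diag(w)), tuple(map(str, range(40))), "functional", 2)
    grid = tn.default_sparsity_grid(0.05, 0.35, 0.1)
    prof = tn.efficiency_profile(cm, grid, n_null=3, null_sparsity_stride=2, seed=0)
    assert prof.e_glob.shape == (4,) and prof.nodal_loc.shape == (4, 40)
    assert np.isfinite(prof.normalized_e_glob[[0, 2]]).all()
    assert np.isnan(prof.normalized_e_glob[[1, 3]]).all()
    assert 0 <= prof.auc_e_glob <= 0.3
    assert prof.auc_e_glob == pytest.approx(tn.auc_over_sparsity(prof.e_glob, grid))
    frame = profiles_to_frame([prof])
    assert len(frame) == 4 and set(frame["subject_id"]) == {"s0"}
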