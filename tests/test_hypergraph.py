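"""Edge-edge graph construction, hyperedge extraction, and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hyperdfc import (
    EdgeIndexMap,
    EdgeTimeSeries,
    Hyperedge,
    Hypergraph,
    edge_edge_correlation,
    extract_hypergraph,
    fdr_binarize,
    node_degree,
    powerlaw_fit,
    shuffle_null,
    size_distribution,
)


def ets_from(weights, tasks=None):
    weights = np.asarray(weights, dtype=float)
    n_edges, n_windows = weights.shape
    # smallest node count whose edge count is >= n_edges, padding with zeros
    n_nodes = 2
    while n_nodes * (n_nodes - 1) // 2 < n_edges:
        n_nodes += 1
    index = EdgeIndexMap(n_nodes)
    full = np.zeros((index.n_edges, n_windows))
    full[:n_edges] = weights
    tasks = tasks or ("task",) * n_windows
    return EdgeTimeSeries(full, index, tasks)


def bh_oracle(p_values, alpha):
    """Step-up rule by exhaustive enumeration of thresholds k*alpha/m."""
    p = np.asarray(p_values)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def bfs_components(adjacency):
    """Brute-force BFS connected components of a dense 0/1 matrix."""
    n = adjacency.shape[0]
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        queue, comp = [start], set()
        seen[start] = True
        while queue:
            u = queue.pop()
            comp.add(u)
            for v in np.flatnonzero(adjacency[u]):
                if not seen[v]:
                    seen[v] = True
                    queue.append(int(v))
        comps.append(frozenset(comp))
    return comps


class TestEdgeEdgeCorrelation:
    def test_diagonal_is_unit_and_never_a_link(self, rng):
        ets = ets_from(rng.standard_normal((5, 20)))
        corr, p = edge_edge_correlation(ets)
        assert np.allclose(np.diag(corr), 1.0)
        graph = fdr_binarize(p, corr, alpha=0.05)
        assert graph.xi.diagonal().sum() == 0

    def test_negated_row_gives_minus_one_and_minimal_p(self, rng):
        x = rng.standard_normal(20)
        ets = ets_from(np.vstack([x, -x, rng.standard_normal(20)]))
        corr, p = edge_edge_correlation(ets)
        assert corr[0, 1] == pytest.approx(-1.0)
        assert p[0, 1] < 1e-12  # a significant negative correlation links too
        graph = fdr_binarize(p, corr, alpha=0.05)
        assert graph.xi_binary[0, 1] == 1

    def test_constant_row_zero_correlation_p_one(self, rng):
        w = np.vstack([np.full(20, 0.3), rng.standard_normal((2, 20))])
        corr, p = edge_edge_correlation(w := ets_from(w))
        assert np.all(corr[0, 1:3] == 0.0)
        assert np.all(p[0, 1:3] == 1.0)

    def test_too_few_windows_rejected(self, rng):
        with pytest.raises(ValueError, match="windows"):
            edge_edge_correlation(ets_from(rng.standard_normal((3, 3))))

    def test_analytic_p_matches_permutation_oracle(self, rng):
        """Two-sided t-transform p-values agree with a 10,000-draw
        permutation p-value within Monte-Carlo error (3 SE)."""
        weights = rng.standard_normal((5, 20))
        ets = ets_from(weights)
        corr, p = edge_edge_correlation(ets)
        n_perm = 10_000
        for i, j in [(0, 1), (1, 2), (3, 4)]:
            observed = abs(corr[i, j])
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(20)
                count += abs(np.corrcoef(weights[i], weights[j][perm])[0, 1]) >= observed
            p_perm = (1 + count) / (1 + n_perm)
            se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
            assert abs(p[i, j] - p_perm) <= 3 * se + 1e-3


class TestFdrBinarize:
    def test_all_null_p_gives_empty_graph(self):
        E = 6
        p = np.ones((E, E))
        corr = np.eye(E)
        graph = fdr_binarize(p, corr)
        assert graph.n_links == 0
        assert extract_hypergraph(graph).cardinality == 0

    def test_all_zero_p_gives_complete_graph_single_hyperedge(self, rng):
        E = 6
        p = np.zeros((E, E))
        corr = np.clip(rng.uniform(0.5, 1, (E, E)), -1, 1)
        corr = (corr + corr.T) / 2
        graph = fdr_binarize(p, corr)
        assert graph.n_links == E * (E - 1) // 2
        hg = extract_hypergraph(graph)
        assert hg.cardinality == 1
        assert hg.hyperedges[0].size == E

    def test_worked_step_up_example(self):
        """Ten p-values at alpha 0.05: the step-up rule keeps the first
        three (p = 0.012 <= 3 * 0.05 / 10, but 0.03 > 4 * 0.05 / 10)."""
        p_flat = [0.001, 0.004, 0.012, 0.03, 0.2, 0.5, 0.7, 0.8, 0.9, 1.0]
        E = 5  # 10 upper-triangle pairs
        p = np.ones((E, E))
        rows, cols = np.triu_indices(E, k=1)
        p[rows, cols] = p_flat
        p[cols, rows] = p_flat
        corr = np.full((E, E), 0.5)
        graph = fdr_binarize(p, corr, alpha=0.05)
        expected = bh_oracle(np.array(p_flat), 0.05)
        got = np.asarray(graph.xi_binary[rows, cols]).ravel() == 1
        np.testing.assert_array_equal(got, expected)
        assert got.sum() == 3

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        E = rng.integers(3, 12)
        flat = rng.uniform(size=E * (E - 1) // 2) ** rng.integers(1, 4)
        p = np.ones((E, E))
        rows, cols = np.triu_indices(E, k=1)
        p[rows, cols] = flat
        p[cols, rows] = flat
        corr = np.full((E, E), 0.3)
        alpha = float(rng.choice([0.01, 0.05, 0.2]))
        graph = fdr_binarize(p, corr, alpha=alpha)
        got = np.asarray(graph.xi_binary[rows, cols]).ravel() == 1
        np.testing.assert_array_equal(got, bh_oracle(flat, alpha))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_link_set_monotone_in_alpha(self, seed):
        rng = np.random.default_rng(seed)
        E = 10
        flat = rng.uniform(size=45) ** 3
        p = np.ones((E, E))
        rows, cols = np.triu_indices(E, k=1)
        p[rows, cols] = flat
        p[cols, rows] = flat
        corr = np.full((E, E), 0.3)
        small = fdr_binarize(p, corr, alpha=0.01)
        large = fdr_binarize(p, corr, alpha=0.1)
        s = np.asarray(small.xi_binary[rows, cols]).ravel() == 1
        l = np.asarray(large.xi_binary[rows, cols]).ravel() == 1
        assert np.all(l[s])  # links at the stricter level survive the looser

    def test_dense_and_sparse_storage_agree(self, rng):
        E = 20
        flat = rng.uniform(size=E * (E - 1) // 2) ** 4
        p = np.ones((E, E))
        rows, cols = np.triu_indices(E, k=1)
        p[rows, cols] = flat
        p[cols, rows] = flat
        corr = np.clip(rng.uniform(-1, 1, (E, E)), -1, 1)
        corr = (corr + corr.T) / 2
        a = fdr_binarize(p, corr, dense=False)
        b = fdr_binarize(p, corr, dense=True)
        np.testing.assert_allclose(a.xi.toarray(), b.xi.toarray())


class TestExtractHypergraph:
    def test_chain_forms_single_hyperedge(self):
        p = np.ones((4, 4))
        for i, j in [(0, 1), (1, 2)]:
            p[i, j] = p[j, i] = 0.0
        graph = fdr_binarize(p, np.full((4, 4), 0.9))
        hg = extract_hypergraph(graph)
        assert hg.cardinality == 1
        assert hg.hyperedges[0].edge_ids == frozenset({0, 1, 2})
        assert hg.hyperedges[0].size == 3
        assert hg.singletons == (3,)

    def test_empty_links_are_all_singletons(self):
        graph = fdr_binarize(np.ones((10, 10)), np.zeros((10, 10)))
        hg = extract_hypergraph(graph)
        assert hg.cardinality == 0
        assert len(hg.singletons) == 10

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_components_match_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        E = 200
        adj = (rng.uniform(size=(E, E)) < 0.006).astype(float)
        adj = np.triu(adj, k=1)
        adj = adj + adj.T
        p = np.where(adj > 0, 0.0, 1.0)
        graph = fdr_binarize(p, adj * 0.8)
        hg = extract_hypergraph(graph)
        oracle = {c for c in bfs_components(adj) if len(c) > 1}
        assert {h.edge_ids for h in hg.hyperedges} == oracle
        singles = {c for c in bfs_components(adj) if len(c) == 1}
        assert {frozenset({s}) for s in hg.singletons} == singles

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_partition_invariant(self, seed):
        rng = np.random.default_rng(seed)
        E = 60
        adj = np.triu((rng.uniform(size=(E, E)) < 0.02).astype(float), k=1)
        adj = adj + adj.T
        hg = extract_hypergraph(fdr_binarize(np.where(adj > 0, 0.0, 1.0), adj))
        assert sum(hg.sizes) + len(hg.singletons) == E


class TestNodeDegree:
    def test_single_hyperedge_counts_each_node_once(self):
        index = EdgeIndexMap(3)
        e01, e12 = index.index_of(0, 1), index.index_of(1, 2)
        hg = Hypergraph(
            (Hyperedge(frozenset({e01, e12})),),
            tuple(set(range(3)) - {e01, e12}),
            3,
        )
        profile = node_degree(hg, index)
        np.testing.assert_array_equal(profile.degree, [1, 1, 1])

    def test_untouched_node_has_zero_degree(self):
        index = EdgeIndexMap(4)
        e = index.index_of(0, 1)
        e2 = index.index_of(0, 2)
        hg = Hypergraph(
            (Hyperedge(frozenset({e, e2})),),
            tuple(set(range(index.n_edges)) - {e, e2}),
            index.n_edges,
        )
        assert node_degree(hg, index).degree[3] == 0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_membership_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        index = EdgeIndexMap(8)
        edge_ids = rng.permutation(index.n_edges)
        cut = rng.integers(2, 10)
        groups = np.array_split(edge_ids[:cut * 2], cut)
        hes = tuple(Hyperedge(frozenset(int(e) for e in g)) for g in groups if len(g) >= 2)
        used = set().union(*(h.edge_ids for h in hes)) if hes else set()
        hg = Hypergraph(hes, tuple(set(range(index.n_edges)) - used), index.n_edges)
        profile = node_degree(hg, index)
        for n in range(8):
            expected = sum(
                any(n in index.pair_of(e) for e in h.edge_ids) for h in hg.hyperedges
            )
            assert profile.degree[n] == expected


class TestShuffleNull:
    def test_rows_are_permutations_with_exact_moments(self, rng):
        ets = ets_from(rng.standard_normal((6, 15)))
        shuffled = shuffle_null(ets, seed=7)
        for e in range(ets.n_edges):
            np.testing.assert_allclose(
                np.sort(shuffled.weights[e]), np.sort(ets.weights[e])
            )
        np.testing.assert_allclose(
            shuffled.weights.mean(axis=1), ets.weights.mean(axis=1)
        )
        np.testing.assert_allclose(
            shuffled.weights.var(axis=1), ets.weights.var(axis=1)
        )

    def test_seed_reproducibility_and_distinctness(self, rng):
        ets = ets_from(rng.standard_normal((6, 30)))
        a = shuffle_null(ets, seed=3)
        b = shuffle_null(ets, seed=3)
        c = shuffle_null(ets, seed=4)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert not np.array_equal(a.weights, c.weights)


def _hg_with_sizes(sizes, n_edges=200):
    hes = []
    next_id = 0
    for s in sizes:
        hes.append(Hyperedge(frozenset(range(next_id, next_id + s))))
        next_id += s
    return Hypergraph(tuple(hes), tuple(range(next_id, n_edges)), n_edges)


class TestSizeDistribution:
    def test_direct_count_example(self):
        dist = size_distribution([_hg_with_sizes([2, 2, 4])])
        assert dist == {2: 3, 3: 1, 4: 1}

    def test_drop_largest_leaves_empty_for_single_hyperedge(self):
        dist = size_distribution([_hg_with_sizes([5])], drop_largest_per_subject=True)
        assert dist == {}

    def test_pooling_over_subjects_matches_enumeration(self):
        pooled = size_distribution([_hg_with_sizes([2, 3]), _hg_with_sizes([3])])
        assert pooled == {2: 3, 3: 2}

    def test_drop_largest_ties_broken_by_lowest_edge_id(self):
        a = Hyperedge(frozenset({0, 1, 2}))
        b = Hyperedge(frozenset({5, 6, 7}))
        hg = Hypergraph((a, b), (3, 4) + tuple(range(8, 20)), 20)
        dist = size_distribution([hg], drop_largest_per_subject=True)
        assert dist == {3: 1}
        assert hg.largest_hyperedge() is a


class TestPowerlawFit:
    def test_recovers_exact_generating_line(self):
        sizes = 2 ** np.arange(1, 7)  # 2..64
        dist = {int(s): 1e4 * s**-2.2 for s in sizes}
        power, intercept = powerlaw_fit(dist)
        assert power == pytest.approx(-2.2, abs=1e-9)
        assert intercept == pytest.approx(1e4, rel=1e-9)

    def test_flat_counts_give_zero_slope(self):
        power, _ = powerlaw_fit({2: 7, 3: 7, 4: 7, 8: 7})
        assert power == pytest.approx(0.0, abs=1e-12)

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            powerlaw_fit({2: 10, 3: 5})

    def test_sampled_power_law_matches_independent_fit(self, rng):
        # discrete power-law sample via inverse transform on a zeta-like tail
        s_values = np.arange(2, 200)
        weights = s_values ** -2.5
        sizes = rng.choice(s_values, size=5000, p=weights / weights.sum())
        dist = {int(s): int(np.sum(sizes >= s)) for s in range(2, sizes.max() + 1)}
        dist = {s: c for s, c in dist.items() if c > 0}
        power, _ = powerlaw_fit(dist)
        xs = np.log10([s for s in dist])
        ys = np.log10([dist[s] for s in dist])
        slope_oracle = stats.linregress(xs, ys).slope
        assert power == pytest.approx(slope_oracle, abs=1e-12)
        assert abs(power - slope_oracle) <= 0.15
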