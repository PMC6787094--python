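"""Thresholding, signed Louvain, cartography, path length, clustering,
rewiring nulls, small-worldness."""

import numpy as np
import pytest

from consdyn import (
    ModulePartition,
    louvain_signed,
    modularity_signed,
    node_cartography,
    proportional_threshold,
    rewire_null,
    small_worldness,
    weighted_clustering,
    weighted_path_length,
)
from conftest import exhaustive_best_partition


class TestProportionalThreshold:
    def test_full_density_keeps_all(self, random_fc):
        g = proportional_threshold(random_fc, 1.0)
        off = ~np.eye(12, dtype=bool)
        assert (g.weights[off] != 0).all() or (random_fc.weights[off] == 0).any()

    def test_top_k_selection(self):
        w = np.zeros((5, 5))
        iu, ju = np.triu_indices(5, 1)
        w[iu, ju] = w[ju, iu] = np.arange(10) / 10.0
        np.fill_diagonal(w, 1.0)
        g = proportional_threshold(w, 0.2)
        assert g.n_edges == 2
        kept = sorted(g.weights[iu, ju][g.weights[iu, ju] > 0])
        assert kept == [0.8, 0.9]

    def test_matches_sort_oracle_with_lexicographic_ties(self, rng):
        n = 8
        vals = rng.choice([0.1, 0.2, 0.3, -0.4], size=(n, n))  # many ties
        w = (vals + vals.T) / 2
        np.fill_diagonal(w, 1.0)
        g = proportional_threshold(w, 0.3)
        iu, ju = np.triu_indices(n, 1)
        order = sorted(range(iu.size), key=lambda k: (-w[iu[k], ju[k]], iu[k], ju[k]))
        k = int(np.ceil(0.3 * iu.size))
        expected = set(order[:k])
        actual = {k2 for k2 in range(iu.size) if g.weights[iu[k2], ju[k2]] != 0}
        assert actual == expected

    def test_negative_edges_drop_out_and_binarize(self, random_fc):
        g = proportional_threshold(random_fc, 0.15, binarize=True)
        assert set(np.unique(g.weights)) <= {0.0, 1.0}
        assert g.weights[g.weights != 0].min() == 1.0


class TestSignedModularity:
    def test_two_cliques_match_exhaustive_optimum(self, two_clique_matrix):
        part = louvain_signed(two_clique_matrix, n_repeats=20, seed=0)
        q_star, assign_star = exhaustive_best_partition(two_clique_matrix)
        assert part.q_value == pytest.approx(q_star, abs=1e-12)
        # cliques recovered
        a = part.assignment
        assert len(set(a[:3])) == 1 and len(set(a[3:])) == 1 and a[0] != a[3]

    def test_uniform_complete_graph_single_module_q_zero(self):
        w = np.full((6, 6), 0.5)
        np.fill_diagonal(w, 0.0)
        assert modularity_signed(w, np.ones(6, int)) == pytest.approx(0.0, abs=1e-12)

    def test_negated_two_cliques_q_matches_direct_formula(self, two_clique_matrix):
        w = -two_clique_matrix
        assign = np.array([1, 1, 1, 2, 2, 2])
        # direct Eq evaluation: no positive weights, so only the negative term
        wn = np.clip(-w, 0, None)
        vn = wn.sum()
        sn = wn.sum(axis=1)
        en = np.outer(sn, sn) / vn
        same = assign[:, None] == assign[None, :]
        expected = -((wn - en)[same].sum()) / (0.0 + vn)
        assert modularity_signed(w, assign) == pytest.approx(expected, abs=1e-12)

    def test_louvain_q_bounded_by_exhaustive_optimum(self, rng):
        for trial in range(6):
            n = int(rng.integers(5, 8))
            a = rng.uniform(-1, 1, (n, n))
            w = (a + a.T) / 2
            np.fill_diagonal(w, 0.0)
            part = louvain_signed(w, n_repeats=30, seed=trial)
            q_star, _ = exhaustive_best_partition(w)
            assert part.q_value <= q_star + 1e-10

    def test_planted_two_module_recovery_many_seeds(self, rng):
        hits = 0
        n_seeds = 30
        for s in range(n_seeds):
            r2 = np.random.default_rng(s)
            w = np.full((10, 10), -0.1) + 0.1 * r2.standard_normal((10, 10))
            w[:5, :5] += 1.0
            w[5:, 5:] += 1.0
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            part = louvain_signed(w, n_repeats=10, seed=s)
            a = part.assignment
            if len(set(a[:5])) == 1 and len(set(a[5:])) == 1 and a[0] != a[9]:
                hits += 1
        assert hits == n_seeds

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            louvain_signed(np.zeros((4, 4)), n_repeats=2, seed=0)

    def test_determinism_under_seed(self, random_fc):
        p1 = louvain_signed(random_fc, n_repeats=10, seed=42)
        p2 = louvain_signed(random_fc, n_repeats=10, seed=42)
        np.testing.assert_array_equal(p1.assignment, p2.assignment)
        assert p1.q_value == p2.q_value


class TestCartography:
    def _partition(self, assignment):
        a = np.asarray(assignment)
        return ModulePartition(assignment=a, n_modules=int(a.max()), q_value=0.0)

    def test_intra_module_node_has_zero_participation(self, two_clique_matrix):
        carto = node_cartography(two_clique_matrix, self._partition([1, 1, 1, 2, 2, 2]))
        np.testing.assert_allclose(carto.participation, 0.0)

    def test_equal_split_participation_half(self):
        # node 0 connects with equal positive strength into both modules
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 1.0  # module 1
        w[0, 3] = w[3, 0] = 1.0  # module 2
        carto = node_cartography(w, self._partition([1, 1, 1, 2, 2]))
        assert carto.participation[0] == pytest.approx(0.5)

    def test_z_zero_at_module_mean_and_hand_evaluation(self):
        # module 1 = {0,1,2} chain: within-strengths 1, 2, 1 -> z = (-1, 2, -1)/sqrt(2/3)...
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        w[3, 3] = 0.0
        carto = node_cartography(w, self._partition([1, 1, 1, 2]))
        own = np.array([1.0, 2.0, 1.0])
        sd = own.std(ddof=0)
        np.testing.assert_allclose(carto.within_module_z[:3], (own - own.mean()) / sd)
        assert carto.within_module_z[3] == 0.0  # singleton module, sigma = 0

    def test_participation_bounded_by_module_count(self, rng):
        w = np.abs(rng.standard_normal((12, 12)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        m = 3
        assign = (np.arange(12) % m) + 1
        carto = node_cartography(w, self._partition(assign))
        assert np.all(carto.participation >= 0.0)
        assert np.all(carto.participation <= 1 - 1 / m + 1e-12)

    def test_strength_conservation(self, random_fc):
        part = louvain_signed(random_fc, n_repeats=10, seed=0)
        carto = node_cartography(random_fc, part)
        np.testing.assert_allclose(
            carto.module_strengths.sum(axis=1), carto.total_positive_strength, atol=1e-12
        )


class TestPathAndClustering:
    def test_single_edge_and_chain(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.25
        g = proportional_threshold(w, 1.0)
        assert weighted_path_length(g).char_path_length == pytest.approx(4.0)

        chain = np.zeros((3, 3))
        chain[0, 1] = chain[1, 0] = chain[1, 2] = chain[2, 1] = 1.0
        gm = weighted_path_length(proportional_threshold(chain, 2 / 3))
        assert gm.char_path_length == pytest.approx(4.0 / 3.0)

    def test_matches_floyd_warshall_oracle(self, rng):
        n = 10
        w = np.abs(rng.standard_normal((n, n)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = proportional_threshold(w, 0.5)
        gm = weighted_path_length(g)
        # dense Floyd-Warshall
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        nz = g.weights > 0
        d[nz] = 1.0 / g.weights[nz]
        for k in range(n):
            d = np.minimum(d, d[:, [k]] + d[[k], :])
        np.testing.assert_allclose(gm.distance_matrix, d, atol=1e-12)
        off = ~np.eye(n, dtype=bool)
        assert gm.char_path_length == pytest.approx(d[off & np.isfinite(d)].mean(), abs=1e-12)

    def test_unreachable_pairs_excluded_and_counted(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        g = proportional_threshold(w, 2 / 6)
        gm = weighted_path_length(g)
        assert gm.n_unreachable_pairs == 8
        assert gm.char_path_length == pytest.approx(1.0)

    def test_triangle_and_star_clustering(self):
        tri = np.zeros((3, 3))
        tri[[0, 0, 1], [1, 2, 2]] = 0.7
        tri = tri + tri.T
        cm = weighted_clustering(proportional_threshold(tri, 1.0))
        np.testing.assert_allclose(cm.clustering, 1.0)

        star = np.zeros((4, 4))
        star[0, 1:] = star[1:, 0] = 0.5
        cm2 = weighted_clustering(proportional_threshold(star, 0.5))
        np.testing.assert_allclose(cm2.clustering, 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        n = 8
        w = np.abs(rng.standard_normal((n, n)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = proportional_threshold(w, 0.6)
        cm = weighted_clustering(g)
        what = g.weights / g.weights.max()
        for i in range(n):
            t = 0.0
            for j in range(n):
                for h in range(n):
                    t += (what[i, j] * what[i, h] * what[j, h]) ** (1 / 3)
            t /= 2.0
            k = (g.weights[i] > 0).sum()
            expected = 2 * t / (k * (k - 1)) if k >= 2 else 0.0
            assert cm.clustering[i] == pytest.approx(expected, abs=1e-12)


class TestRewireAndSmallWorld:
    def test_rewire_preserves_degrees_and_weights(self, rng):
        w = np.abs(rng.standard_normal((15, 15)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = proportional_threshold(w, 0.3)
        null = rewire_null(g, swaps_per_edge=20, seed=1)
        np.testing.assert_array_equal(
            (null.weights > 0).sum(axis=1), (g.weights > 0).sum(axis=1)
        )
        np.testing.assert_allclose(
            np.sort(null.weights[np.triu_indices(15, 1)]),
            np.sort(g.weights[np.triu_indices(15, 1)]),
        )

    def test_rewiring_destroys_modular_clustering(self):
        # modular graph: nulls have lower mean clustering
        rng = np.random.default_rng(0)
        w = np.full((16, 16), 0.05)
        for b in range(4):
            w[4 * b : 4 * b + 4, 4 * b : 4 * b + 4] = 0.9
        w += 0.01 * rng.standard_normal((16, 16))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = proportional_threshold(w, 0.2)
        c_orig = weighted_clustering(g).clustering.mean()
        c_nulls = [
            weighted_clustering(rewire_null(g, swaps_per_edge=20, seed=s)).clustering.mean()
            for s in range(30)
        ]
        assert np.mean(c_nulls) < c_orig

    def test_single_density_identity(self, rng):
        a = rng.uniform(-1, 1, (20, 20))
        w = (a + a.T) / 2
        np.fill_diagonal(w, 1.0)
        res = small_worldness(w, densities=[0.3], n_nulls=5, seed=3, swaps_per_edge=10)
        d = res.per_density[0.3]
        assert res.s_value == pytest.approx((d["c"] / d["c_random"]) / (d["l"] / d["l_random"]))

    def test_node_relabelling_invariance(self, rng, random_fc):
        perm = rng.permutation(12)
        wp = random_fc.weights[np.ix_(perm, perm)]
        g1 = proportional_threshold(random_fc, 0.4)
        g2 = proportional_threshold(wp, 0.4)
        np.testing.assert_allclose(
            sorted(weighted_clustering(g1).clustering), sorted(weighted_clustering(g2).clustering),
            atol=1e-12,
        )
        assert weighted_path_length(g1).char_path_length == pytest.approx(
            weighted_path_length(g2).char_path_length, abs=1e-12
        )
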