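import numpy as np
import pytest
import skbio

from gutcomm.io import read_newick
from gutcomm.preprocess import AbundanceTable
from gutcomm.stability import UNASSIGNED
from gutcomm.stratify import (
    Clustering,
    DistanceMatrix,
    bray_curtis_matrix,
    calinski_harabasz,
    choose_k,
    community_subtable,
    pam,
    pam_brute_force,
    pcoa_coordinates,
    taxonomy_cladogram,
    unifrac,
    unifrac_matrix,
)
from conftest import make_lineage
from oracles import best_medoids


def blob_distances(centers, sizes, spread, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.concatenate([rng.normal(c, spread, size=(s, 2))
                          for c, s in zip(centers, sizes)])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    ids = [f"s{i:02d}" for i in range(len(pts))]
    labels = np.repeat(np.arange(len(sizes)), sizes)
    return DistanceMatrix(ids, d), labels


class TestCommunitySubtable:
    def setup_method(self):
        self.table = AbundanceTable(
            ["A", "B", "C"], ["s1", "s2"],
            np.array([[0.2, 0.1], [0.3, 0.4], [0.5, 0.5]]))
        self.assignment = {"A": 0, "B": 0, "C": 1}

    def test_rows_restricted(self):
        sub = community_subtable(self.table, self.assignment, 0)
        assert sub.genus_ids == ["A", "B"]

    def test_values_not_renormalized(self):
        sub = community_subtable(self.table, self.assignment, 0)
        assert np.allclose(sub.values, [[0.2, 0.1], [0.3, 0.4]])

    def test_renormalize_switch(self):
        sub = community_subtable(self.table, self.assignment, 0, renormalize=True)
        assert np.allclose(sub.values.sum(axis=0), 1.0)

    def test_unknown_community_error(self):
        with pytest.raises(ValueError):
            community_subtable(self.table, self.assignment, 9)

    def test_unassigned_excluded(self):
        assignment = {"A": 0, "B": UNASSIGNED, "C": 0}
        sub = community_subtable(self.table, assignment, 0)
        assert sub.genus_ids == ["A", "C"]


class TestUnifrac:
    def test_identical_vectors_zero(self, four_leaf_newick):
        tree = read_newick(four_leaf_newick)
        x = [0.1, 0.2, 0.3, 0.4]
        assert unifrac(tree, x, x, list("ABCD")) == pytest.approx(0.0)
        assert unifrac(tree, x, x, list("ABCD"), "unweighted") == pytest.approx(0.0)

    def test_disjoint_star_tree_unweighted_one(self):
        tree = read_newick("(A:1,B:1,C:1,D:1);")
        d = unifrac(tree, [1, 1, 0, 0], [0, 0, 1, 1], list("ABCD"), "unweighted")
        assert d == pytest.approx(1.0)

    def test_hand_computed_four_leaf(self, four_leaf_newick):
        # x on A only, y on C only: every covered branch is unshared
        tree = read_newick(four_leaf_newick)
        x, y = [1, 0, 0, 0], [0, 0, 1, 0]
        assert unifrac(tree, x, y, list("ABCD"), "unweighted") == pytest.approx(1.0)
        # weighted: u = 1*|1-0| + 1*|1-0| (A, AB) + same for C side = 4
        # c = tipdist(A)*1 + tipdist(C)*1 = 2 + 2 = 4
        assert unifrac(tree, x, y, list("ABCD")) == pytest.approx(1.0)

    def test_matches_skbio_on_integer_counts(self):
        from skbio.diversity.beta import unweighted_unifrac, weighted_unifrac
        from gutcomm.synthetic import simulate_tree
        rng = np.random.default_rng(0)
        names = [f"g{i}" for i in range(12)]
        for seed in range(5):
            tree = simulate_tree(names, seed=seed)
            x = rng.integers(0, 20, len(names))
            y = rng.integers(0, 20, len(names))
            if x.sum() == 0 or y.sum() == 0:
                continue
            ours_u = unifrac(tree, x, y, names, "unweighted")
            ours_w = unifrac(tree, x, y, names)
            assert ours_u == pytest.approx(
                unweighted_unifrac(x, y, taxa=names, tree=tree), abs=1e-10)
            assert ours_w == pytest.approx(
                weighted_unifrac(x, y, taxa=names, tree=tree, normalized=True),
                abs=1e-10)

    def test_range_and_symmetry(self):
        from gutcomm.synthetic import simulate_tree
        rng = np.random.default_rng(1)
        names = [f"g{i}" for i in range(8)]
        tree = simulate_tree(names, seed=3)
        for _ in range(20):
            x = rng.uniform(0, 1, 8)
            y = rng.uniform(0, 1, 8)
            for mode in ("unweighted", "weighted_normalized"):
                d1 = unifrac(tree, x, y, names, mode)
                d2 = unifrac(tree, y, x, names, mode)
                assert 0.0 <= d1 <= 1.0 + 1e-12
                assert d1 == pytest.approx(d2)

    def test_unweighted_triangle_inequality(self):
        from gutcomm.synthetic import simulate_tree
        rng = np.random.default_rng(2)
        names = [f"g{i}" for i in range(6)]
        tree = simulate_tree(names, seed=4)
        for _ in range(20):
            vecs = (rng.uniform(0, 1, 6) * rng.integers(0, 2, 6) + 1e-6
                    for _ in range(3))
            a, b, c = vecs
            dab = unifrac(tree, a, b, names, "unweighted")
            dbc = unifrac(tree, b, c, names, "unweighted")
            dac = unifrac(tree, a, c, names, "unweighted")
            assert dac <= dab + dbc + 1e-9

    def test_leaf_mismatch_error(self, four_leaf_newick):
        tree = read_newick(four_leaf_newick)
        with pytest.raises(ValueError, match="absent"):
            unifrac(tree, [1, 1], [1, 1], ["A", "Zzz"])

    def test_all_zero_vector_error(self, four_leaf_newick):
        tree = read_newick(four_leaf_newick)
        with pytest.raises(ValueError):
            unifrac(tree, [0, 0, 0, 0], [1, 0, 0, 0], list("ABCD"))


class TestUnifracMatrix:
    def test_identical_samples_zero_matrix(self, four_leaf_newick):
        tree = read_newick(four_leaf_newick)
        t = AbundanceTable(list("ABCD"), ["s1", "s2"],
                           np.tile([[0.25]], (4, 2)))
        m = unifrac_matrix(tree, t)
        assert np.allclose(m.values, 0.0)

    def test_row_order_invariance(self, four_leaf_newick):
        tree = read_newick(four_leaf_newick)
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.1, 1, size=(4, 3))
        t1 = AbundanceTable(list("ABCD"), ["s1", "s2", "s3"], vals)
        order = [2, 0, 3, 1]
        t2 = AbundanceTable([list("ABCD")[i] for i in order],
                            ["s1", "s2", "s3"], vals[order])
        assert np.allclose(unifrac_matrix(tree, t1).values,
                           unifrac_matrix(tree, t2).values)

    def test_bray_curtis_alternative(self):
        t = AbundanceTable(["A", "B"], ["s1", "s2"],
                           np.array([[0.5, 0.0], [0.5, 1.0]]))
        m = bray_curtis_matrix(t)
        assert m.values[0, 1] == pytest.approx(0.5)


class TestPam:
    def test_two_blobs_match_brute_force(self):
        dist, labels = blob_distances([(0, 0), (10, 10)], [5, 5], 0.5)
        cl = pam(dist, 2)
        obj = dist.values[np.arange(10), [cl.medoids[l] for l in cl.labels]].sum()
        best_obj, _ = best_medoids(dist.values, 2)
        assert obj == pytest.approx(best_obj)
        assert len({tuple(cl.labels[:5]), tuple(cl.labels[5:])}) == 2

    def test_k_equals_n(self):
        dist, _ = blob_distances([(0, 0)], [5], 1.0)
        cl = pam(dist, 5)
        assert sorted(cl.medoids) == list(range(5))

    def test_k1_is_argmin_total_distance(self):
        dist, _ = blob_distances([(0, 0)], [7], 2.0, seed=3)
        cl = pam(dist, 1)
        assert cl.medoids[0] == int(np.argmin(dist.values.sum(axis=1)))

    def test_k_out_of_range(self):
        dist, _ = blob_distances([(0, 0)], [4], 1.0)
        with pytest.raises(ValueError):
            pam(dist, 5)

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_exhaustive_for_small_n(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, size=(7, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0)
        dist = DistanceMatrix([f"s{i}" for i in range(7)], 0.5 * (d + d.T))
        for k in range(1, 8):
            cl = pam(dist, k)
            obj = dist.values[:, cl.medoids].min(axis=1).sum()
            best_obj, _ = best_medoids(dist.values, k)
            assert obj == pytest.approx(best_obj, abs=1e-9)


class TestCalinskiHarabasz:
    def test_two_far_blobs(self):
        dist, labels = blob_distances([(0, 0), (50, 50)], [6, 6], 0.3)
        cl2 = pam(dist, 2)
        cl3 = pam(dist, 3)
        assert calinski_harabasz(dist, cl2) > calinski_harabasz(dist, cl3)

    def test_hand_computed_on_four_points(self):
        # two pairs at mutual distance 1, pairs separated by 10
        ids = ["a", "b", "c", "d"]
        d = np.array([[0, 1, 10, 10],
                      [1, 0, 10, 10],
                      [10, 10, 0, 1],
                      [10, 10, 1, 0]], dtype=float)
        dist = DistanceMatrix(ids, d)
        cl = Clustering(ids, np.array([0, 0, 1, 1]), [0, 2])
        # W = 2 * (1/(2*2)) * (2*1^2) = 1
        # T = (1/8) * (4*1 + 8*100) = 100.5
        # CH = ((T-W)/(k-1)) / (W/(n-k)) = 99.5 / 0.5 = 199
        assert calinski_harabasz(dist, cl) == pytest.approx(199.0)

    def test_scale_invariance(self):
        dist, _ = blob_distances([(0, 0), (5, 5)], [5, 5], 1.0)
        cl = pam(dist, 2)
        scaled = DistanceMatrix(dist.sample_ids, dist.values * 10)
        assert calinski_harabasz(dist, cl) == pytest.approx(
            calinski_harabasz(scaled, cl))

    def test_k1_error(self):
        dist, _ = blob_distances([(0, 0)], [5], 1.0)
        with pytest.raises(ValueError):
            calinski_harabasz(dist, pam(dist, 1))

    def test_zero_within_dispersion_inf(self):
        ids = ["a", "b", "c", "d"]
        vals = np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                         [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float)
        dist = DistanceMatrix(ids, vals)
        cl = Clustering(ids, np.array([0, 0, 1, 1]), [0, 2])
        with pytest.warns(UserWarning):
            assert calinski_harabasz(dist, cl) == np.inf


class TestChooseK:
    def test_planted_three(self):
        dist, _ = blob_distances([(0, 0), (20, 0), (0, 20)], [6, 6, 6], 0.5)
        assert choose_k(dist).k == 3

    def test_planted_two(self):
        dist, _ = blob_distances([(0, 0), (20, 20)], [7, 7], 0.5)
        assert choose_k(dist).k == 2

    @staticmethod
    def unifrac_fixture(seed, k=3, per=7, n_genera=18, noise_conc=6.0,
                        sig=14.0):
        """UniFrac-structured samples: per-cluster signature genera plus
        isotropic Dirichlet noise on a star tree."""
        rng = np.random.default_rng(seed)
        names = [f"g{i}" for i in range(n_genera)]
        tree = read_newick("(" + ",".join(f"{n}:1" for n in names) + ");")
        cols = []
        for c in range(k):
            base = np.full(n_genera, noise_conc)
            base[2 * c] += sig
            base[2 * c + 1] += sig * 0.5
            for _ in range(per):
                cols.append(rng.dirichlet(base))
        table = AbundanceTable(names, [f"s{i:02d}" for i in range(k * per)],
                               np.array(cols).T)
        return unifrac_matrix(tree, table)

    def test_recovery_rate_on_unifrac_structured_data(self):
        # spec property: >= 90/100 at strong separation; scaled to 20 seeds
        for planted in (2, 3):
            hits = sum(choose_k(self.unifrac_fixture(seed, k=planted)).k
                       == planted for seed in range(20))
            assert hits >= 18


class TestPcoa:
    def test_three_equidistant_points(self):
        ids = ["a", "b", "c"]
        d = np.full((3, 3), 2.0)
        np.fill_diagonal(d, 0)
        dist = DistanceMatrix(ids, d)
        coords = pcoa_coordinates(dist, n_axes=2)
        # reconstructed pairwise distances match the equilateral configuration
        rec = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.allclose(rec, d, atol=1e-9)
        # eigenvalues equal for the two axes
        G = coords.T @ coords
        assert G[0, 0] == pytest.approx(G[1, 1])

    def test_duplicate_sample_identical_coordinates(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 0, 3], [0, 0, 3], [3, 3, 0]], dtype=float)
        dist = DistanceMatrix(ids, d)
        coords = pcoa_coordinates(dist)
        assert np.allclose(coords[0], coords[1])

    def test_line_positions_recovered(self):
        pos = np.array([0.0, 1.0, 3.0, 7.0, 8.0])
        d = np.abs(pos[:, None] - pos[None, :])
        dist = DistanceMatrix([f"s{i}" for i in range(5)], d)
        axis1 = pcoa_coordinates(dist, n_axes=1)[:, 0]
        assert np.array_equal(np.argsort(axis1), np.argsort(pos)) or \
            np.array_equal(np.argsort(-axis1), np.argsort(pos))

    def test_sign_convention_deterministic(self):
        dist, _ = blob_distances([(0, 0), (5, 5)], [4, 4], 1.0)
        a = pcoa_coordinates(dist)
        b = pcoa_coordinates(dist)
        assert np.allclose(a, b)
        nz = np.nonzero(np.abs(a[:, 0]) > 1e-12)[0]
        assert a[nz[0], 0] > 0


class TestTaxonomyCladogram:
    def test_leaves_are_genera_and_unifrac_runs(self):
        lineages = {
            "Alpha": make_lineage("Alpha"),
            "Beta": make_lineage("Beta"),
            "Gamma": make_lineage("Gamma", order="OrderB"),
        }
        tree = taxonomy_cladogram(lineages)
        assert sorted(t.name for t in tree.tips()) == ["Alpha", "Beta", "Gamma"]
        d = unifrac(tree, [1, 0, 0], [0, 0, 1], ["Alpha", "Beta", "Gamma"])
        assert 0 < d <= 1
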