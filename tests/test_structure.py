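"""PCA, IBS/neighbors, pairwise F_ST, Nei distance, NJ tree, kNN network."""

import networkx as nx
import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from snppop.dataset import MISSING, make_dataset
from snppop.simulate import SimulationConfig, simulate_balding_nichols
from snppop.structure import (
    ibs_matrix,
    knn_network,
    nearest_neighbors,
    nei_distance,
    nj_tree,
    nm_from_fst,
    pairwise_fst,
    pca,
    standardize_genotypes,
)

from conftest import random_dataset


def polymorphic_dataset(rng, n=20, m=60, n_pops=1):
    p = rng.uniform(0.2, 0.8, size=m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    # guarantee polymorphism
    calls[0] = 0
    calls[1] = 2
    pops = [f"P{i % n_pops + 1}" for i in range(n)]
    return make_dataset(calls, populations=pops)


class TestPCA:
    def test_two_duplicate_groups_separate_on_pc1(self, rng):
        proto = rng.binomial(2, rng.uniform(0.2, 0.8, 40), size=(2, 40)).astype(np.int8)
        calls = np.vstack([np.tile(proto[0], (5, 1)), np.tile(proto[1], (5, 1))])
        from snppop.qc import filter_maf

        d, _ = filter_maf(make_dataset(calls), 0.0)  # drop monomorphic columns
        res = pca(d, 4)
        pc1 = res.eigenvectors[:, 0]
        assert res.pct_variance[0] == pytest.approx(1.0, abs=1e-9)
        assert np.ptp(np.sign(pc1[:5])) == 0 and np.ptp(np.sign(pc1[5:])) == 0
        assert np.sign(pc1[0]) != np.sign(pc1[9])

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        d = polymorphic_dataset(rng)
        res = pca(d, 6)
        X, _ = standardize_genotypes(d)
        # independent oracle: full SVD of the standardized matrix
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        lam = s**2 / X.shape[1]
        for k in range(6):
            assert res.eigenvalues[k] == pytest.approx(lam[k], abs=1e-8)
            dot = abs(float(u[:, k] @ res.eigenvectors[:, k]))
            assert dot == pytest.approx(1.0, abs=1e-8)  # same direction up to sign

    def test_pct_variance_non_increasing(self, rng):
        d = polymorphic_dataset(rng)
        res = pca(d, 8)
        assert np.all(np.diff(res.pct_variance) <= 1e-12)
        assert np.all(res.pct_variance >= 0)

    def test_three_populations_cluster(self):
        cfg = SimulationConfig(
            n_populations=3, n_samples_per_pop=20, n_variants_per_chrom=2000, target_fst=0.15, seed=55
        )
        d, _ = simulate_balding_nichols(cfg)
        from snppop.qc import filter_maf

        d, _ = filter_maf(d, 0.05)
        res = pca(d, 2)
        from sklearn.metrics import silhouette_score

        labels = d.samples["population"].to_numpy()
        assert silhouette_score(res.eigenvectors[:, :2], labels) > 0.5

    def test_monomorphic_variant_rejected(self):
        d = make_dataset(np.zeros((4, 3), dtype=np.int8))
        with pytest.raises(ValueError, match="MAF"):
            pca(d)


class TestIBS:
    def test_duplicate_samples_have_ibs_one(self, rng):
        d = polymorphic_dataset(rng, n=4)
        d.calls[1] = d.calls[0]
        ibs = ibs_matrix(d)
        assert ibs[0, 1] == pytest.approx(1.0)

    def test_opposite_homozygotes_have_ibs_zero(self):
        d = make_dataset(np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8))
        assert ibs_matrix(d)[0, 1] == pytest.approx(0.0)

    def test_matches_bruteforce_tally(self, rng):
        d = random_dataset(rng, n=8, m=40, missing_rate=0.1)
        ibs = ibs_matrix(d)
        for i in range(8):
            for j in range(8):
                gi, gj = d.calls[i], d.calls[j]
                ok = (gi != MISSING) & (gj != MISSING)
                expected = np.mean((2 - np.abs(gi[ok] - gj[ok])) / 2)
                assert ibs[i, j] == pytest.approx(expected, abs=1e-12)


class TestNearestNeighbors:
    def test_duplicated_pair_are_mutual_rank_one(self, rng):
        d = polymorphic_dataset(rng, n=6)
        d.calls[3] = d.calls[0]
        ibs = ibs_matrix(d)
        nn = nearest_neighbors(ibs, list(d.samples["sample_id"]), k=3)
        top = nn[nn["rank"] == 1].set_index("sample_id")["neighbor_id"]
        assert top["S1"] == "S4" and top["S4"] == "S1"

    def test_distances_sorted_ascending(self, rng):
        d = polymorphic_dataset(rng, n=10)
        nn = nearest_neighbors(ibs_matrix(d), list(d.samples["sample_id"]), k=5)
        for _, g in nn.groupby("sample_id"):
            dist = g.sort_values("rank")["ibs_distance"].to_numpy()
            assert np.all(np.diff(dist) >= 0)

    def test_requires_enough_samples(self, rng):
        d = polymorphic_dataset(rng, n=4)
        with pytest.raises(ValueError):
            nearest_neighbors(ibs_matrix(d), list(d.samples["sample_id"]), k=5)


class TestPairwiseFst:
    def test_nm_formula(self):
        assert nm_from_fst(0.2) == pytest.approx(1.0)
        assert nm_from_fst(0.01) == pytest.approx(24.75)
        assert np.isinf(nm_from_fst(0.0))

    def test_slatkin_linearization(self, bn_three_pop_small):
        data, _ = bn_three_pop_small
        res = pairwise_fst(data, n_permutations=20, seed=3)
        i, j = 0, 1
        assert res.slatkin_linearized[i, j] == pytest.approx(
            res.fst[i, j] / (1 - res.fst[i, j])
        )
        assert res.nm[i, j] == pytest.approx((1 / res.fst[i, j] - 1) / 4)
        assert np.allclose(res.fst, res.fst.T)
        assert np.all(np.diag(res.fst) == 0)

    def test_split_single_population_null(self, rng):
        # one panmictic deme relabeled as two: fst ~ 0, p not extreme
        p = rng.uniform(0.2, 0.8, 400)
        calls = rng.binomial(2, p, size=(40, 400)).astype(np.int8)
        d = make_dataset(calls, populations=["A"] * 20 + ["B"] * 20)
        res = pairwise_fst(d, n_permutations=99, seed=11)
        assert abs(res.fst[0, 1]) < 0.01
        assert res.p_values[0, 1] > 0.05

    def test_differentiated_pair_significant(self, bn_three_pop_small):
        data, _ = bn_three_pop_small
        res = pairwise_fst(data, n_permutations=99, seed=7)
        assert res.fst[0, 1] > 0.05
        assert res.p_values[0, 1] <= 0.05


class TestNeiDistance:
    def test_identical_frequencies_give_zero(self, rng):
        base = polymorphic_dataset(rng, n=10)
        calls = np.vstack([base.calls, base.calls])  # identical frequency vectors
        d = make_dataset(calls, populations=["X"] * 10 + ["Y"] * 10)
        res = nei_distance(d)
        assert res.nei_d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_single_variant(self):
        # p_x = (1, 0), p_y = (0.5, 0.5): D = -ln(0.5 / sqrt(1 * 0.5)) = 0.3466
        calls = np.array([[0], [0], [1], [1]], dtype=np.int8)
        d = make_dataset(calls, populations=["X", "X", "Y", "Y"])
        res = nei_distance(d)
        assert res.nei_d[0, 1] == pytest.approx(0.34657, abs=1e-4)

    def test_symmetric_zero_diagonal(self, bn_three_pop_small):
        data, _ = bn_three_pop_small
        res = nei_distance(data)
        assert np.allclose(res.nei_d, res.nei_d.T)
        assert np.all(np.diag(res.nei_d) == 0)


def _tree_distances(newick: str):
    tree = TreeNode.read([newick])
    tips = sorted(t.name for t in tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


def _random_additive_matrix(rng, n_leaves):
    """Random tree -> additive distance matrix (path lengths)."""
    labels = [f"T{i}" for i in range(n_leaves)]
    # random topology via random sequential joining with positive lengths
    import itertools

    nodes = {lab: None for lab in labels}
    tree = TreeNode.read([f"({labels[0]}:0.0,{labels[1]}:0.0);"])
    # simpler: build random newick by recursive splitting
    def build(leaves):
        if len(leaves) == 1:
            return f"{leaves[0]}:{rng.uniform(0.1, 1.0):.4f}"
        k = rng.integers(1, len(leaves))
        left, right = leaves[:k], leaves[k:]
        return f"({build(left)},{build(right)}):{rng.uniform(0.1, 1.0):.4f}"

    perm = list(rng.permutation(labels))
    newick = f"({build(perm[: len(perm) // 2])},{build(perm[len(perm) // 2 :])});"
    dists = _tree_distances(newick)
    D = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                key = (a, b) if (a, b) in dists else (b, a)
                D[i, j] = D[j, i] = dists[key]
    return D, labels


class TestNJ:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        newick = nj_tree(D, ["a", "b", "c"])
        d = _tree_distances(newick)
        # v_a = (5 + 9 - 10)/2 = 2, v_b = 3, v_c = 7
        assert d[("a", "b")] == pytest.approx(5.0)
        assert d[("a", "c")] == pytest.approx(9.0)
        assert d[("b", "c")] == pytest.approx(10.0)

    @pytest.mark.parametrize("n_leaves", [4, 6, 8])
    def test_recovers_additive_matrices(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for rep in range(10):
            D, labels = _random_additive_matrix(rng, n_leaves)
            newick = nj_tree(D, labels)
            got = _tree_distances(newick)
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i < j:
                        key = (a, b) if (a, b) in got else (b, a)
                        assert got[key] == pytest.approx(D[i, j], abs=1e-6)

    def test_agrees_with_skbio_on_additive_input(self):
        rng = np.random.default_rng(33)
        D, labels = _random_additive_matrix(rng, 6)
        ours = _tree_distances(nj_tree(D, labels))
        theirs = _tree_distances(str(skbio_nj(DistanceMatrix(D, labels))))
        for key, val in ours.items():
            k2 = key if key in theirs else (key[1], key[0])
            assert theirs[k2] == pytest.approx(val, abs=1e-6)

    def test_too_few_taxa_raises(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])


class TestKnnNetwork:
    def test_complete_graph_at_max_k(self, rng):
        d = polymorphic_dataset(rng, n=8)
        ibs = ibs_matrix(d)
        G = knn_network(1 - ibs, list(d.samples["sample_id"]), list(d.samples["population"]), k=7)
        assert nx.is_connected(G)
        assert G.number_of_edges() == 8 * 7 // 2

    def test_separated_populations_form_components(self):
        cfg = SimulationConfig(
            n_populations=2, n_samples_per_pop=10, n_variants_per_chrom=500, target_fst=0.4, seed=21
        )
        d, _ = simulate_balding_nichols(cfg)
        ibs = ibs_matrix(d)
        G = knn_network(1 - ibs, list(d.samples["sample_id"]), list(d.samples["population"]), k=2)
        comps = list(nx.connected_components(G))
        pops = {}
        for c in comps:
            for node in c:
                pops[node] = min(comps.index(c), 1)
        labels = d.samples.set_index("sample_id")["population"]
        # every component is population-pure
        for c in comps:
            assert len({labels[n] for n in c}) == 1

    def test_no_self_loops(self, rng):
        d = polymorphic_dataset(rng, n=10)
        G = knn_network(
            1 - ibs_matrix(d), list(d.samples["sample_id"]), list(d.samples["population"]), k=3
        )
        assert all(u != v for u, v in G.edges)
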