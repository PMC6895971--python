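"""Differentiation and structure: theta estimators, AMOVA, pruning, PCA, NJ."""

import numpy as np
import pytest

import autozyg as az
from autozyg.popdiff import reynolds_theta
from tests.conftest import make_genotypes


def theta_oracle_per_marker(p1, p2, n1, n2):
    """Independent single-marker coancestry estimator, averaged ratio-of-sums.

    Second implementation of the same moment corrections, written scalar-wise.
    """
    nums, dens = [], []
    for a, b, m, n in zip(p1, p2, n1, n2):
        s1, s2 = a * (1 - a), b * (1 - b)
        num = (a - b) ** 2 - s1 / (2 * m - 1) - s2 / (2 * n - 1)
        den = num + 2 * m * s1 / (2 * m - 1) + 2 * n * s2 / (2 * n - 1)
        nums.append(num)
        dens.append(den)
    return sum(nums) / sum(dens)


class TestReynolds:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(1)
        codes = rng.binomial(2, rng.uniform(0.2, 0.8, 1000), size=(60, 1000)).astype(np.int8)
        pops = np.array(["A"] * 30 + ["B"] * 30, dtype=object)
        g = make_genotypes(codes, populations=pops)
        dr, theta = az.reynolds_distance(g)
        assert abs(dr.values[0, 1]) < 0.01

    def test_fixed_alternative_alleles_maximal(self):
        codes = np.vstack([np.full((10, 50), 2), np.full((10, 50), 0)]).astype(np.int8)
        pops = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        g = make_genotypes(codes, populations=pops)
        dr, theta = az.reynolds_distance(g)
        assert theta.values[0, 1] == pytest.approx(1.0)
        assert dr.values[0, 1] > 5

    def test_matches_independent_oracle_on_balding_nichols(self, bn_two_pops):
        g, _ = bn_two_pops
        sub = g.subset(marker_idx=np.arange(2000))
        _, theta = az.reynolds_distance(sub)
        fa = sub.by_population("A").allele_frequency()
        fb = sub.by_population("B").allele_frequency()
        expected = theta_oracle_per_marker(fa, fb, np.full(2000, 50), np.full(2000, 50))
        assert theta.values[0, 1] == pytest.approx(expected, rel=1e-9)

    def test_dr_is_neglog_of_theta(self, bn_two_pops):
        g, _ = bn_two_pops
        dr, theta = az.reynolds_distance(g)
        np.testing.assert_allclose(dr.values[0, 1],
                                   -np.log(1 - theta.values[0, 1]), rtol=1e-12)


class TestWeirCockerham:
    def test_identical_populations_small_theta(self):
        rng = np.random.default_rng(4)
        codes = rng.binomial(2, rng.uniform(0.2, 0.8, 2000), size=(80, 2000)).astype(np.int8)
        pops = np.array(["A"] * 40 + ["B"] * 40, dtype=object)
        g = make_genotypes(codes, populations=pops)
        assert az.weir_cockerham_fst(g, mode="global") <= 0.01

    def test_hand_worked_single_marker(self):
        """n = (10, 10), p = (0.9, 0.1), all-het-carrier composition:
        a = 2.84/9, denominator 3.69/9 -> theta = 2.84/3.69."""
        pop1 = [2] * 8 + [1] * 2          # p(counted) = 0.9, h = 0.2
        pop2 = [0] * 8 + [1] * 2          # p(counted) = 0.1, h = 0.2
        codes = np.array(pop1 + pop2, dtype=np.int8)[:, None]
        pops = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        g = make_genotypes(codes, populations=pops)
        theta = az.weir_cockerham_fst(g, mode="per-marker").iloc[0]
        assert theta == pytest.approx(2.84 / 3.69, rel=1e-12)

    def test_monomorphic_marker_undefined(self):
        codes = np.array([[2, 1], [2, 0], [2, 2], [2, 1]], dtype=np.int8)
        pops = np.array(["A", "A", "B", "B"], dtype=object)
        g = make_genotypes(codes, populations=pops)
        per = az.weir_cockerham_fst(g, mode="per-marker")
        assert np.isnan(per.iloc[0])

    def test_balding_nichols_truth_bracket(self, bn_two_pops):
        """Global theta on F = 0.1 divergence lands within +/- 0.02 of F."""
        g, _ = bn_two_pops
        assert az.weir_cockerham_fst(g, mode="global") == pytest.approx(0.1, abs=0.02)


class TestAMOVA:
    def test_no_structure_null(self):
        """Random labels: among-population share near zero, p usually > 0.05."""
        rng = np.random.default_rng(6)
        codes = rng.binomial(2, 0.5, size=(40, 300)).astype(np.int8)
        hits = 0
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(40)
            pops = np.where(perm < 20, "A", "B").astype(object)
            g = make_genotypes(codes, populations=pops)
            res = az.amova(g, n_perm=99, seed=seed)
            assert res.pct_among < 5.0
            hits += res.p_value > 0.05
        assert hits >= 8

    def test_fixed_divergence_extreme(self):
        codes = np.vstack([np.full((10, 100), 2), np.full((10, 100), 0)]).astype(np.int8)
        pops = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        res = az.amova(make_genotypes(codes, populations=pops), n_perm=99, seed=0)
        assert res.pct_among > 95.0
        assert res.p_value < 0.05

    def test_components_sum_to_100(self, bn_two_pops):
        g, _ = bn_two_pops
        sub = g.subset(marker_idx=np.arange(300))
        res = az.amova(sub, n_perm=99, seed=3)
        assert res.pct_among + res.pct_within == pytest.approx(100.0)


class TestLDPrune:
    def test_duplicated_pair_keeps_one(self):
        rng = np.random.default_rng(8)
        col = rng.binomial(2, 0.5, 40).astype(np.int8)
        other = rng.binomial(2, 0.5, 40).astype(np.int8)
        g = make_genotypes(np.column_stack([col, col, other]))
        kept = az.ld_prune(g)
        assert 0 in kept and 1 not in kept and 2 in kept

    def test_independent_markers_untouched(self):
        rng = np.random.default_rng(9)
        codes = rng.binomial(2, 0.5, size=(200, 30)).astype(np.int8)
        g = make_genotypes(codes)
        assert len(az.ld_prune(g)) == 30

    def test_correlated_triplet_manual_trace(self):
        """Three identical markers inside one window: greedy pairwise rule drops
        the two later duplicates, everything else survives."""
        rng = np.random.default_rng(10)
        cols = [rng.binomial(2, 0.5, 80).astype(np.int8) for _ in range(57)]
        dup = rng.binomial(2, 0.5, 80).astype(np.int8)
        codes = np.column_stack(cols[:20] + [dup, dup, dup] + cols[20:])
        g = make_genotypes(codes)
        kept = set(az.ld_prune(g, r2_threshold=0.5))
        assert 20 in kept and 21 not in kept and 22 not in kept
        assert len(kept) == 58


class TestPCA:
    def test_separates_divergent_populations(self):
        cfg = az.SimConfig(seed=83, populations={"A": 50, "B": 50},
                           divergence_f={"A": 0.2, "B": 0.2},
                           genotyping_error=0.0, missingness=0.0)
        g, _ = az.simulate_balding_nichols(cfg)
        coords, _ = az.pca(g)
        a = coords.loc[coords["population"] == "A", "PC1"].to_numpy()
        b = coords.loc[coords["population"] == "B", "PC1"].to_numpy()
        assert max(a.min(), b.min()) > min(a.max(), b.max())  # zero overlap

    def test_fractions_sorted_and_bounded(self, bn_two_pops):
        g, _ = bn_two_pops
        _, fr = az.pca(g.subset(marker_idx=np.arange(500)))
        assert (np.diff(fr) <= 1e-12).all()
        assert fr.sum() <= 1.0 + 1e-9

    def test_duplicating_samples_preserves_fractions(self):
        rng = np.random.default_rng(12)
        codes = rng.binomial(2, rng.uniform(0.2, 0.8, 200), size=(20, 200)).astype(np.int8)
        g1 = make_genotypes(codes)
        g2 = make_genotypes(np.vstack([codes, codes]))
        _, f1 = az.pca(g1, n_components=5)
        _, f2 = az.pca(g2, n_components=5)
        np.testing.assert_allclose(f1, f2, atol=1e-9)


def random_additive_matrix(n_taxa, seed):
    """Patristic distances of a random binary tree with positive branch lengths."""
    rng = np.random.default_rng(seed)
    import itertools
    nodes = {i: [i] for i in range(n_taxa)}       # node id -> leaves below
    dist = np.zeros((n_taxa, n_taxa))
    depth = {i: 0.0 for i in range(n_taxa)}
    leaf_extra = np.zeros(n_taxa)
    active = list(range(n_taxa))
    add = np.zeros((n_taxa, n_taxa))
    # build by random agglomeration with random branch lengths
    next_id = n_taxa
    lengths = {}
    parent = {}
    children = {}
    for _ in range(n_taxa - 1):
        i, j = rng.choice(len(active), 2, replace=False)
        a, b = active[i], active[j]
        la, lb = rng.uniform(0.5, 3.0, 2)
        children[next_id] = [(a, la), (b, lb)]
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1

    # leaf-to-leaf distances by DFS from the root
    root = active[0]
    dists_to_leaves = {}

    def walk(node, acc):
        if node < n_taxa:
            dists_to_leaves[node] = acc
            return
        for child, ln in children[node]:
            walk(child, acc + [(child, ln)])

    # distance between two leaves = sum of branch lengths on the unique path
    paths = {}

    def collect(node, path):
        if node < n_taxa:
            paths[node] = path
            return
        for child, ln in children[node]:
            collect(child, path + [(node, child, ln)])

    collect(root, [])
    D = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            ea = {(x, y): l for x, y, l in paths[a]}
            eb = {(x, y): l for x, y, l in paths[b]}
            d = (sum(l for k, l in ea.items() if k not in eb)
                 + sum(l for k, l in eb.items() if k not in ea))
            D[a, b] = D[b, a] = d
    return D


class TestNJ:
    def test_four_taxon_additive_recovery(self):
        """The classic additive matrix returns the generating topology with the
        generating branch lengths (patristic distances match exactly)."""
        D = np.array([[0, 5, 9, 10], [5, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]], float)
        dm = az.DistanceMatrix(["A", "B", "C", "D"], D, "additive")
        import skbio
        tree = skbio.TreeNode.read([az.nj_tree(dm)])
        for (x, y), want in {("A", "B"): 5, ("A", "C"): 9, ("A", "D"): 10,
                             ("B", "C"): 10, ("B", "D"): 11, ("C", "D"): 7}.items():
            assert tree.find(x).distance(tree.find(y)) == pytest.approx(want)

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (8, 4)])
    def test_additive_matrices_recovered_exactly(self, n_taxa, seed):
        import skbio
        D = random_additive_matrix(n_taxa, seed)
        labels = [f"t{i}" for i in range(n_taxa)]
        tree = skbio.TreeNode.read([az.nj_tree(az.DistanceMatrix(labels, D, "additive"))])
        for a in range(n_taxa):
            for b in range(a + 1, n_taxa):
                got = tree.find(labels[a]).distance(tree.find(labels[b]))
                assert got == pytest.approx(D[a, b], rel=1e-9, abs=1e-9)

    def test_three_taxa_unique_topology(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        nwk = az.nj_tree(az.DistanceMatrix(["A", "B", "C"], D, "d"))
        assert nwk.count(",") == 2 and nwk.endswith(";")

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            az.nj_tree(az.DistanceMatrix(["A", "B"], np.zeros((2, 2)), "d"))

    def test_agrees_with_skbio_on_additive_input(self):
        """Independent oracle: scikit-bio's NJ on the same additive matrix yields
        the same patristic distances."""
        import skbio
        D = random_additive_matrix(6, 9)
        labels = [f"t{i}" for i in range(6)]
        mine = skbio.TreeNode.read([az.nj_tree(az.DistanceMatrix(labels, D, "d"))])
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        for a in range(6):
            for b in range(a + 1, 6):
                got = mine.find(labels[a]).distance(mine.find(labels[b]))
                ref = theirs.find(labels[a]).distance(theirs.find(labels[b]))
                assert got == pytest.approx(ref, rel=1e-9)

    def test_ibs_population_distance_feeds_tree(self, bn_two_pops):
        g, _ = bn_two_pops
        # add a third synthetic population so NJ applies
        rng = np.random.default_rng(15)
        extra = rng.binomial(2, 0.5, size=(10, g.n_markers)).astype(np.int8)
        codes = np.vstack([g.codes, extra])
        pops = np.concatenate([g.populations, np.full(10, "C", dtype=object)])
        g3 = make_genotypes(codes, populations=pops)
        dm = az.ibs_distance(g3, level="population")
        assert dm.values[0, 1] > 0
        nwk = az.nj_tree(dm)
        assert nwk.count("A") == 1 and nwk.endswith(";")
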