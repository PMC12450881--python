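import itertools

import numpy as np
import pytest

import germdiv as gd
from germdiv.io import DistanceMatrix, TreeNode


def naive_upgma_cophenetic(labels, matrix):
    """Reference UPGMA via the defining property: the distance between two
    clusters is the plain average of the original pairwise distances of
    their members. Returns the cophenetic matrix (leaf pair -> 2 x merge
    height). Independent of the production implementation's size-weighted
    recurrence."""
    n = len(labels)
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))

    def cdist(a, b):
        return np.mean([matrix[i, j] for i in a for j in b])

    while len(clusters) > 1:
        best, bd = None, np.inf
        for x, y in itertools.combinations(range(len(clusters)), 2):
            d = cdist(clusters[x], clusters[y])
            if d < bd - 1e-15:
                bd, best = d, (x, y)
        x, y = best
        for i in clusters[x]:
            for j in clusters[y]:
                coph[i, j] = coph[j, i] = bd
        merged = clusters[x] + clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [merged]
    return coph


def cophenetic_from_tree(tree: TreeNode, labels):
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    coph = np.zeros((n, n))

    def walk(node):
        if node.is_leaf:
            return [node.label]
        below = [walk(c) for c in node.children]
        for a, b in itertools.combinations(range(len(below)), 2):
            for la in below[a]:
                for lb in below[b]:
                    coph[idx[la], idx[lb]] = coph[idx[lb], idx[la]] = 2 * node.height
        return [l for group in below for l in group]

    walk(tree)
    return coph


class TestAccessionDistance:
    def _bm(self, rows, primers=2):
        arr = np.array(rows)
        return gd.BandMatrix(
            [f"a{i}" for i in range(arr.shape[0])],
            [f"P{j}" for j in range(arr.shape[1] // 2)],
            arr,
        )

    def test_identical_rows_have_zero_distance(self):
        dm = gd.accession_distance(self._bm([[1, 0, 1, 0], [1, 0, 1, 0]]))
        assert dm.matrix[0, 1] == 0.0

    def test_disjoint_presences_have_dice_one(self):
        dm = gd.accession_distance(self._bm([[1, 0, 1, 0], [0, 1, 0, 1]]))
        assert dm.matrix[0, 1] == 1.0

    def test_half_overlap_counts(self):
        # rows 1100 vs 1010: a=1 shared, b=1, c=1 -> dice d = 0.5
        dm = gd.accession_distance(self._bm([[1, 1, 0, 0], [1, 0, 1, 0]]))
        assert dm.matrix[0, 1] == pytest.approx(1 - 2 / 4)

    def test_simple_matching_counts_mismatch_fraction(self):
        dm = gd.accession_distance(
            self._bm([[1, 1, 0, 0], [1, 0, 1, 0]]), method="simple_matching"
        )
        assert dm.matrix[0, 1] == pytest.approx(2 / 4)

    def test_missing_primer_slots_excluded_when_requested(self):
        # accession b failed at primer 1 (0,0): only primer 2 is compared
        dm = gd.accession_distance(
            self._bm([[1, 0, 1, 1], [0, 0, 1, 1]]), exclude_missing=True
        )
        assert dm.matrix[0, 1] == 0.0

    def test_no_comparable_slots_is_error(self):
        with pytest.raises(ValueError, match="no comparable"):
            gd.accession_distance(
                self._bm([[1, 0, 0, 0], [0, 0, 1, 0]]), exclude_missing=True
            )


class TestUPGMA:
    def test_three_taxon_worked_example(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
        )
        tree = gd.upgma(dm)
        assert gd.write_newick(tree) == "((A:1,B:1):1,C:2);"

    def test_two_taxa_merge_at_half_distance(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 0.6], [0.6, 0.0]]))
        tree = gd.upgma(dm)
        assert tree.height == pytest.approx(0.3)

    def test_equidistant_taxa_tie_break_is_lexicographic(self):
        m = np.full((4, 4), 1.0)
        np.fill_diagonal(m, 0.0)
        dm = DistanceMatrix(["d", "c", "b", "a"], m)
        t1 = gd.write_newick(gd.upgma(dm))
        t2 = gd.write_newick(gd.upgma(DistanceMatrix(["a", "b", "c", "d"], m)))
        assert t1 == t2  # input order does not matter, labels do
        assert t1.startswith("(((a:0.5,b:0.5)")

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_naive_reference_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        condensed = rng.uniform(0.1, 2.0, size=n * (n - 1) // 2)
        m = np.zeros((n, n))
        m[np.triu_indices(n, 1)] = condensed
        m = m + m.T
        labels = [f"t{i}" for i in range(n)]
        tree = gd.upgma(DistanceMatrix(labels, m))
        np.testing.assert_allclose(
            cophenetic_from_tree(tree, labels),
            naive_upgma_cophenetic(labels, m),
            atol=1e-10,
        )

    def test_agrees_with_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(99)
        n = 12
        m = np.zeros((n, n))
        m[np.triu_indices(n, 1)] = rng.uniform(0.5, 3.0, size=n * (n - 1) // 2)
        m = m + m.T
        labels = [f"t{i:02d}" for i in range(n)]
        tree = gd.upgma(DistanceMatrix(labels, m))
        sp = squareform(cophenet(linkage(squareform(m), method="average")))
        np.testing.assert_allclose(cophenetic_from_tree(tree, labels), sp, atol=1e-10)

    def test_reconstructs_ultrametric_input_exactly(self):
        # build a random ultrametric via a random tree, then recover it
        inner1 = TreeNode(height=0.2, children=[TreeNode(label="A"), TreeNode(label="B")])
        inner2 = TreeNode(height=0.35, children=[inner1, TreeNode(label="C")])
        root = TreeNode(height=0.8, children=[inner2, TreeNode(label="D")])
        labels = ["A", "B", "C", "D"]
        m = cophenetic_from_tree(root, labels)
        tree = gd.upgma(DistanceMatrix(labels, m))
        np.testing.assert_allclose(cophenetic_from_tree(tree, labels), m, atol=1e-12)


class TestCutTree:
    def _tree(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
        )
        return gd.upgma(dm)

    def test_k_one_is_single_group(self):
        groups = gd.cut_tree(self._tree(), 1)
        assert set(groups.values()) == {1}

    def test_k_n_is_singletons(self):
        groups = gd.cut_tree(self._tree(), 3)
        assert sorted(groups.values()) == [1, 2, 3]

    def test_highest_merge_removed_first(self):
        groups = gd.cut_tree(self._tree(), 2)
        assert groups["A"] == groups["B"] != groups["C"]

    def test_groups_nest_as_k_increases(self, panel_genotypes):
        bm = gd.genotype_to_band(panel_genotypes.subset(panel_genotypes.accession_ids[:40]))
        tree = gd.upgma(gd.accession_distance(bm))
        prev = gd.cut_tree(tree, 2)
        for k in range(3, 8):
            cur = gd.cut_tree(tree, k)
            # each new group must be wholly inside one previous group
            for g in set(cur.values()):
                members = [l for l, v in cur.items() if v == g]
                assert len({prev[m] for m in members}) == 1
            prev = cur

    def test_out_of_range_k_rejected(self):
        with pytest.raises(ValueError):
            gd.cut_tree(self._tree(), 0)
        with pytest.raises(ValueError):
            gd.cut_tree(self._tree(), 4)


class TestMarkerPCA:
    def test_one_band_difference_separates_two_clones(self):
        rows = np.array([[1, 0, 1, 0]] * 5 + [[1, 0, 0, 1]] * 5)
        bm = gd.BandMatrix([f"a{i}" for i in range(10)], ["P1", "P2"], rows)
        coords, _ = gd.marker_pca(bm, 2)
        side = coords[:, 0] > 0
        assert len(set(side[:5])) == 1 and len(set(side[5:])) == 1
        assert side[0] != side[5]

    def test_explained_proportions_decrease_and_sum_below_one(self):
        rng = np.random.default_rng(12)
        bm = gd.BandMatrix(
            [f"a{i}" for i in range(50)],
            [f"P{j}" for j in range(15)],
            rng.integers(0, 2, size=(50, 30)),
        )
        _, explained = gd.marker_pca(bm, 5)
        assert (np.diff(explained) <= 1e-12).all()
        assert explained.sum() <= 1.0 + 1e-12

    def test_duplicated_accessions_coincide(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 2, size=(6, 8))
        rows[4] = rows[1]
        bm = gd.BandMatrix(
            [f"a{i}" for i in range(6)], [f"P{j}" for j in range(4)], rows
        )
        coords, _ = gd.marker_pca(bm, 3)
        np.testing.assert_allclose(coords[4], coords[1], atol=1e-10)

    def test_constant_matrix_rejected(self):
        bm = gd.BandMatrix(["a", "b"], ["P1"], np.ones((2, 2), dtype=int))
        with pytest.raises(ValueError, match="constant"):
            gd.marker_pca(bm)
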