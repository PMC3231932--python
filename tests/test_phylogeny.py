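"""p-distance, neighbor-joining, bootstrap and Newick serialization."""

import numpy as np
import pytest

from replichore.phylogeny import (
    Alignment,
    DistanceMatrix,
    PairwiseDeletionError,
    PhyloTree,
    TreeNode,
    bootstrap_support,
    neighbor_joining,
    p_distance_matrix,
    read_newick,
    write_newick,
)
from replichore.simulate import simulate_alignment


def random_tree(n_taxa, rng, min_len=0.05, max_len=1.0):
    nodes = [
        TreeNode(name=f"t{i}", length=float(rng.uniform(min_len, max_len)))
        for i in range(n_taxa)
    ]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(
            length=float(rng.uniform(min_len, max_len)), children=[nodes[i], nodes[j]]
        )
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    return PhyloTree(TreeNode(children=nodes))


class TestPDistance:
    def test_identical_rows_zero(self):
        d = p_distance_matrix(Alignment(["a", "b"], ["ACGT", "ACGT"]))
        assert d.d[0, 1] == 0.0

    def test_one_mismatch_in_hundred(self):
        row_a = "A" * 100
        row_b = "C" + "A" * 99
        d = p_distance_matrix(Alignment(["a", "b"], [row_a, row_b]))
        assert d.d[0, 1] == pytest.approx(0.01)

    def test_masked_mismatch_discarded(self):
        # oracle: hand count on a 10-column toy alignment
        a = "ACGTACGTAC"
        b = "ANGTACGTCC"  # mismatch at col 2 masked by N; real mismatch col 9
        d = p_distance_matrix(Alignment(["a", "b"], [a, b]))
        assert d.d[0, 1] == pytest.approx(1 / 9)

    def test_gaps_discarded_pairwise(self):
        a = "AC-TAC"
        b = "ACGTAC"
        d = p_distance_matrix(Alignment(["a", "b"], [a, b]))
        assert d.d[0, 1] == 0.0

    def test_zero_retained_sites_names_pair(self):
        with pytest.raises(PairwiseDeletionError, match="a.*b"):
            p_distance_matrix(Alignment(["a", "b"], ["NNNN", "ACGT"]))

    def test_jukes_cantor_option(self):
        row_a = "A" * 90 + "C" * 10
        row_b = "A" * 100
        d = p_distance_matrix(Alignment(["a", "b"], [row_a, row_b]), model="jc")
        assert d.d[0, 1] == pytest.approx(-0.75 * np.log(1 - 4 * 0.1 / 3))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(["a", "b", "c"], np.array(
            [[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]]
        ))
        tree = neighbor_joining(D)
        lengths = {next(l.name for l in c.leaves()) if c.is_leaf else None: c.length
                   for c in tree.root.children}
        # three-point formulas: la=(dab+dac-dbc)/2 etc.
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_four_taxon_known_tree_recovered_exactly(self):
        # build an additive matrix from a tree with branch lengths 1..5
        #   ((A:1,B:2):5,C:3,D:4)
        gen = PhyloTree(TreeNode(children=[
            TreeNode(length=5.0, children=[
                TreeNode(name="A", length=1.0), TreeNode(name="B", length=2.0)
            ]),
            TreeNode(name="C", length=3.0),
            TreeNode(name="D", length=4.0),
        ]))
        D = gen.leaf_distances()
        tree = neighbor_joining(D)
        assert set(tree.bipartitions()) == {frozenset({"C", "D"})} or \
               set(tree.bipartitions()) == {frozenset({"A", "B"})}
        np.testing.assert_allclose(tree.leaf_distances().d, D.d, atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_additive_matrices_inverted_exactly(self, seed):
        rng = np.random.default_rng(seed)
        gen = random_tree(int(rng.integers(5, 9)), rng)
        D = gen.leaf_distances()
        tree = neighbor_joining(D)
        assert set(tree.bipartitions()) == set(gen.bipartitions())
        assert np.abs(tree.leaf_distances().d - D.d).max() < 1e-9

    def test_agrees_with_independent_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        gen = random_tree(7, rng)
        D = gen.leaf_distances()
        ours = neighbor_joining(D)
        theirs = skbio.tree.nj(
            skbio.DistanceMatrix(D.d, ids=D.taxa)
        )
        their_bips = set()
        taxa = set(D.taxa)
        anchor = min(taxa)
        for node in theirs.non_tips():
            under = {t.name for t in node.tips()}
            if 1 < len(under) < len(taxa) - 1:
                side = under if anchor not in under else taxa - under
                their_bips.add(frozenset(side))
        assert set(ours.bipartitions()) == their_bips

    def test_input_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
            )


class TestBootstrap:
    def test_congruent_sites_give_full_support(self):
        rng = np.random.default_rng(2)
        gen = random_tree(4, rng, min_len=0.1, max_len=0.3)
        aln, _ = simulate_alignment(gen, 400, seed=8)
        boot = bootstrap_support(aln, replicates=100, seed=3)
        supports = [n.support for n in boot.tree.bipartitions().values()]
        assert supports and all(s == 100.0 for s in supports)
        assert boot.completed == 100

    def test_identical_rows_have_no_internal_structure(self):
        aln = Alignment(["a", "b", "c", "d"], ["ACGT" * 10] * 4)
        boot = bootstrap_support(aln, replicates=10, seed=1)
        assert boot.tree.bipartitions() == {} or all(
            n.support is not None for n in boot.tree.bipartitions().values()
        )

    def test_two_seeds_agree_within_sampling_error(self):
        rng = np.random.default_rng(9)
        gen = random_tree(5, rng, min_len=0.02, max_len=0.2)
        aln, _ = simulate_alignment(gen, 300, seed=14)
        b1 = bootstrap_support(aln, replicates=100, seed=100)
        b2 = bootstrap_support(aln, replicates=100, seed=200)
        s1 = {bp: n.support for bp, n in b1.tree.bipartitions().items()}
        s2 = {bp: n.support for bp, n in b2.tree.bipartitions().items()}
        assert set(s1) == set(s2)
        for bp in s1:
            p = (s1[bp] + s2[bp]) / 200
            se = 100 * np.sqrt(max(p * (1 - p), 1e-4) / 100)
            assert abs(s1[bp] - s2[bp]) <= 4 * se + 1

    def test_seeded_determinism(self):
        rng = np.random.default_rng(21)
        gen = random_tree(5, rng)
        aln, _ = simulate_alignment(gen, 200, seed=5)
        b1 = bootstrap_support(aln, replicates=30, seed=77)
        b2 = bootstrap_support(aln, replicates=30, seed=77)
        assert b1.tree.newick() == b2.tree.newick()


class TestNewick:
    def test_three_taxon_shape(self):
        tree = neighbor_joining(
            DistanceMatrix(["A", "B", "C"], np.array(
                [[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float
            ))
        )
        text = tree.newick(decimals=1)
        assert text.startswith("(") and text.endswith(";")
        assert text.count(",") == 2 and "A:" in text

    def test_roundtrip_via_independent_parser(self, tmp_path):
        rng = np.random.default_rng(6)
        gen = random_tree(6, rng)
        aln, _ = simulate_alignment(gen, 500, seed=4)
        boot = bootstrap_support(aln, replicates=20, seed=2)
        p = write_newick(boot.tree, tmp_path / "t.nwk")
        back = read_newick(p)
        assert set(back.taxa) == set(boot.tree.taxa)
        assert set(back.bipartitions()) == set(boot.tree.bipartitions())
        ours = {bp: n.support for bp, n in boot.tree.bipartitions().items()}
        theirs = {bp: n.support for bp, n in back.bipartitions().items()}
        assert ours == theirs
        d0, d1 = boot.tree.leaf_distances(), back.leaf_distances()
        order = [d1.taxa.index(t) for t in d0.taxa]
        np.testing.assert_allclose(d0.d, d1.d[np.ix_(order, order)], atol=1e-9)

    def test_names_with_spaces_quoted(self, tmp_path):
        tree = PhyloTree(TreeNode(children=[
            TreeNode(name="L. sanfranciscensis", length=0.1),
            TreeNode(name="L. brevis", length=0.2),
            TreeNode(name="out", length=0.3),
        ]))
        p = write_newick(tree, tmp_path / "q.nwk")
        assert "'L. sanfranciscensis'" in p.read_text()
        back = read_newick(p)
        assert "L. sanfranciscensis" in back.taxa
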