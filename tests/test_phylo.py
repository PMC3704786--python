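"""Poisson distances, neighbor joining and bootstrap support."""

import math

import numpy as np
import pytest

from novocomp.phylo import (
    AlignmentBlock,
    DistanceMatrix,
    _bipartitions,
    bootstrap,
    distance_matrix,
    nj_tree,
    poisson_distance,
)


class TestPoissonDistance:
    def test_identical_rows(self):
        assert poisson_distance("ACDEF", "ACDEF") == 0.0

    def test_closed_form(self):
        # 3 mismatches in 10 shared columns: -ln(0.7)
        assert poisson_distance("A" * 7 + "CCC", "A" * 7 + "GGG") == pytest.approx(
            -math.log(0.7)
        )

    def test_pairwise_deletion_hand_count(self):
        # columns: (A,A) (−,C) (D,D) (E,−) (F,Y) -> shared 3, mismatch 1
        assert poisson_distance("A-DEF", "ACD-Y") == pytest.approx(-math.log(1 - 1 / 3))

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="[Ss]aturated"):
            poisson_distance("AAAA", "CCCC")

    def test_no_shared_columns_raises(self):
        with pytest.raises(ValueError):
            poisson_distance("A--", "-CC")

    def test_symmetry(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY-")
        a = "".join(rng.choice(aa, 60))
        b = "".join(rng.choice(aa, 60))
        try:
            assert poisson_distance(a, b) == poisson_distance(b, a)
        except ValueError:
            pass


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.4, 0.7], [0.4, 0, 0.9], [0.7, 0.9, 0]])
        tree = nj_tree(DistanceMatrix(list("abc"), d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.1, abs=1e-9)
        assert lengths["b"] == pytest.approx(0.3, abs=1e-9)
        assert lengths["c"] == pytest.approx(0.6, abs=1e-9)

    def test_additive_four_taxon_recovery(self, rng):
        """NJ recovers the generating split of random additive matrices."""
        for _ in range(25):
            ea, eb, ec, ed, em = rng.uniform(0.05, 1.0, 5)
            d = np.array(
                [
                    [0, ea + eb, ea + em + ec, ea + em + ed],
                    [ea + eb, 0, eb + em + ec, eb + em + ed],
                    [ea + em + ec, eb + em + ec, 0, ec + ed],
                    [ea + em + ed, eb + em + ed, ec + ed, 0],
                ]
            )
            tree = nj_tree(DistanceMatrix(list("abcd"), d))
            splits = _bipartitions(tree, frozenset("abcd"))
            assert splits == {frozenset("cd")}

    def test_scaling_invariance(self, rng):
        d = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        d[iu] = rng.uniform(0.2, 2.0, len(iu[0]))
        d = d + d.T
        taxa = list("abcde")
        t1 = nj_tree(DistanceMatrix(taxa, d))
        t2 = nj_tree(DistanceMatrix(taxa, 2 * d))
        assert _bipartitions(t1, frozenset(taxa)) == _bipartitions(t2, frozenset(taxa))

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_non_finite_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(list("abc"), d))

    def test_matches_skbio_on_random_matrix(self, rng):
        """Independent cross-check against scikit-bio's NJ topology."""
        import skbio

        n = 6
        pts = rng.uniform(0, 1, (n, 4))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0)
        taxa = list("abcdef")
        mine = nj_tree(DistanceMatrix(taxa, d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, taxa))
        assert _bipartitions(mine, frozenset(taxa)) == _bipartitions(
            theirs, frozenset(taxa)
        )


def _clade_alignment(rng, n_cols=300):
    """Three well-separated pairs from a common ancestor."""
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    base = "".join(rng.choice(aa, n_cols))

    def mut(s, n):
        s = list(s)
        for i in rng.choice(len(s), n, replace=False):
            s[i] = "W" if s[i] != "W" else "Y"
        return "".join(s)

    a = mut(base, 30)
    b = mut(a, 10)
    c = mut(base, 40)
    d = mut(c, 12)
    e = mut(base, 80)
    f = mut(e, 15)
    return AlignmentBlock(list("abcdef"), [a, b, c, d, e, f])


class TestBootstrap:
    def test_known_topology_high_support(self, rng):
        """Generating pairs (a,b), (c,d), (e,f) recovered with support >= 90."""
        aln = _clade_alignment(rng)
        tree = bootstrap(aln, replicates=200, seed=5)
        splits = _bipartitions(tree, frozenset("abcdef"))
        # the two informative splits around the (a,b) anchor
        assert frozenset("cd") in splits and frozenset("ef") in splits
        for node in tree.non_tips(include_self=False):
            if node.name is not None:
                assert int(node.name) >= 90

    def test_uninformative_alignment_full_support(self):
        """Identical rows except one divergent taxon: every replicate gives
        the same (tie-broken) topology, so all splits sit at 100."""
        base = "ACDEFGHIKL" * 5
        rows = [base] * 4 + ["W" * 20 + base[20:]]  # one taxon 40% divergent
        aln = AlignmentBlock(list("abcde"), rows)
        tree = bootstrap(aln, replicates=50, seed=1)
        for node in tree.non_tips(include_self=False):
            if node.name is not None:
                assert node.name == "100"

    def test_seed_stability_within_sampling_error(self, rng):
        aln = _clade_alignment(rng)
        t1 = bootstrap(aln, replicates=300, seed=10)
        t2 = bootstrap(aln, replicates=300, seed=11)
        s1 = {frozenset(t.name for t in n.tips()): n.bootstrap for n in t1.non_tips()}
        s2 = {frozenset(t.name for t in n.tips()): n.bootstrap for n in t2.non_tips()}
        for k in s1:
            # binomial sampling bound: ~4 sigma at p=0.5, n=300 is < 12 points
            assert abs(s1[k] - s2[k]) <= 12.0

    def test_newick_output_parses(self, rng):
        import skbio

        aln = _clade_alignment(rng)
        tree = bootstrap(aln, replicates=50, seed=2)
        back = skbio.TreeNode.read([str(tree)])
        assert {t.name for t in back.tips()} == set("abcdef")


class TestAlignmentIO:
    def test_read_fasta(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">t1\nAC-DE\n>t2\nACIDE\n>t3\nACID-\n")
        aln = AlignmentBlock.read_fasta(p)
        assert aln.taxon_ids == ["t1", "t2", "t3"]
        assert aln.n_cols == 5
        dm = distance_matrix(aln)
        assert dm.d[0, 1] == 0.0  # t1 vs t2: shared columns all identical

    def test_ragged_rejected(self):
        with pytest.raises(ValueError):
            AlignmentBlock(["a", "b"], ["ACD", "AC"])
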