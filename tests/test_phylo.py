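"""NJ phylogeny: distances, tree recovery, bootstrap, rooting, condensation."""

import numpy as np
import pytest

from swfscreen.phylo import (
    Clade,
    DistanceMatrix,
    PhyloTree,
    bipartitions,
    bootstrap_support,
    condense,
    leaf_path_lengths,
    nj_tree,
    p_distance,
    parse_newick,
    root_with_outgroup,
    to_newick,
)
from swfscreen.seq import ProteinSequence
from swfscreen.simulate import simulate_alignment


def prot(id, residues):
    return ProteinSequence(id=id, residues=residues)


class TestPDistance:
    def test_examples(self):
        aln = [
            prot("a", "ACDEFGHIKL"),
            prot("b", "ACDEFGHIKL"),
            prot("c", "ACDEFGHIVV"),
        ]
        dm = p_distance(aln)
        i = {t: k for k, t in enumerate(dm.taxa)}
        assert dm.matrix[i["a"], i["b"]] == 0.0
        assert dm.matrix[i["a"], i["c"]] == pytest.approx(0.2)

    def test_pairwise_deletion(self):
        aln = [
            prot("a", "AC-EF"),
            prot("b", "ACD-F"),
            prot("c", "ACDEF"),
        ]
        dm = p_distance(aln)
        i = {t: k for k, t in enumerate(dm.taxa)}
        # a vs b compare only columns 1,2,5 -> identical
        assert dm.matrix[i["a"], i["b"]] == 0.0

    def test_no_comparable_columns_raises(self):
        aln = [prot("a", "A--"), prot("b", "-C-"), prot("c", "AC-")]
        with pytest.raises(ValueError, match="no comparable columns"):
            p_distance(aln)


def random_additive_case(n_taxa, seed):
    """Random binary tree with random branch lengths and its path-length
    (additive) distance matrix, computed by an independent path oracle."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [Clade(name=l) for l in labels[:3]]
    root = Clade(children=nodes)
    for node in nodes:
        node.length = float(rng.uniform(0.1, 1.0))
    attachable = list(nodes)
    for label in labels[3:]:
        target = attachable[int(rng.integers(0, len(attachable)))]
        # split target's pendant edge and hang the new leaf
        parent = next(n for n in root.walk() if target in n.children)
        mid = Clade(length=target.length * float(rng.uniform(0.2, 0.8)))
        target_new_len = target.length - mid.length
        parent.children[parent.children.index(target)] = mid
        target.length = target_new_len
        leaf = Clade(name=label, length=float(rng.uniform(0.1, 1.0)))
        mid.children = [target, leaf]
        attachable += [leaf, mid]
    tree = PhyloTree(root=root)
    paths = leaf_path_lengths(tree)
    M = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                M[i, j] = M[j, i] = paths[(a, b) if a < b else (b, a)]
    return tree, DistanceMatrix(labels, M)


class TestNeighbourJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]]),
        )
        tree = nj_tree(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["a"] == pytest.approx(0.1, abs=1e-12)
        assert lengths["b"] == pytest.approx(0.3, abs=1e-12)
        assert lengths["c"] == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (8, 4)])
    def test_recovers_additive_matrices_exactly(self, n_taxa, seed):
        source, dm = random_additive_case(n_taxa, seed)
        est = nj_tree(dm)
        assert set(bipartitions(est)) == set(bipartitions(source))
        est_paths = leaf_path_lengths(est)
        src_paths = leaf_path_lengths(source)
        for pair, d in src_paths.items():
            assert est_paths[pair] == pytest.approx(d, abs=1e-9)

    def test_equidistant_ties_are_deterministic(self):
        labels = ["a", "b", "c", "d"]
        M = np.ones((4, 4)) - np.eye(4)
        trees = {to_newick(nj_tree(DistanceMatrix(labels, M)).root) for _ in range(5)}
        assert len(trees) == 1

    def test_agrees_with_reference_implementation(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(9)
        pts = rng.random((7, 3))
        M = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(7)]
        mine = nj_tree(DistanceMatrix(labels, M))
        ref = skbio_nj(SkDM(M, labels))
        all_l = frozenset(labels)
        ref_bips = set()
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            if min(all_l) in side:
                side = all_l - side
            if len(side) >= 2 and len(all_l - side) >= 2:
                ref_bips.add(side)
        assert set(bipartitions(mine)) == ref_bips


class TestBootstrap:
    def make_strong_alignment(self):
        # clade {c,d} differs from everything else at half the columns
        base = "A" * 40
        variant = "V" * 20 + "A" * 20
        return [
            prot("a", base), prot("b", base),
            prot("c", variant), prot("d", variant),
            prot("e", base[:-1] + "C"),
        ]

    def test_strong_clade_gets_full_support(self):
        tree = bootstrap_support(self.make_strong_alignment(), n_replicates=100, seed=1)
        supports = {frozenset(("c", "d")): None}
        for bip, node in bipartitions(tree).items():
            if bip == frozenset(("c", "d")):
                supports[bip] = node.support
        assert supports[frozenset(("c", "d"))] == 100.0

    def test_same_seed_same_supports(self):
        a = bootstrap_support(self.make_strong_alignment(), 25, seed=7)
        b = bootstrap_support(self.make_strong_alignment(), 25, seed=7)
        assert to_newick(a.root) == to_newick(b.root)

    def test_supports_bounded(self):
        tree = bootstrap_support(self.make_strong_alignment(), 25, seed=3)
        for node in tree.root.walk():
            if node.support is not None:
                assert 0.0 <= node.support <= 100.0


class TestRooting:
    def test_outgroup_is_root_child_and_paths_preserved(self):
        _, dm = random_additive_case(5, seed=6)
        tree = nj_tree(dm)
        rooted = root_with_outgroup(tree, "t3")
        assert rooted.rooted
        names = [c.name for c in rooted.root.children]
        assert "t3" in names
        before = leaf_path_lengths(tree)
        after = leaf_path_lengths(rooted)
        for pair, d in before.items():
            assert after[pair] == pytest.approx(d, abs=1e-9)

    def test_missing_outgroup_raises(self):
        _, dm = random_additive_case(4, seed=2)
        with pytest.raises(ValueError, match="'nope'"):
            root_with_outgroup(nj_tree(dm), "nope")

    def test_reroot_roundtrip_is_isomorphic(self):
        _, dm = random_additive_case(6, seed=8)
        t1 = root_with_outgroup(nj_tree(dm), "t0")
        t2 = root_with_outgroup(t1, "t5")
        t3 = root_with_outgroup(t2, "t0")
        assert set(bipartitions(t1)) == set(bipartitions(t3))
        p1, p3 = leaf_path_lengths(t1), leaf_path_lengths(t3)
        for pair, d in p1.items():
            assert p3[pair] == pytest.approx(d, abs=1e-9)


class TestCondense:
    def build_supported_tree(self):
        newick = "(((a:1,b:1)30:1,(c:1,d:1)35:1)80:1,e:1,f:1);"
        return parse_newick(newick)

    def test_boundary_rule(self):
        tree = self.build_supported_tree()
        condensed = condense(tree, 35)
        kept = {n.support for n in condensed.root.walk() if n.support is not None}
        assert kept == {35.0, 80.0}  # 30 collapsed; 35 retained (>= rule)

    def test_cutoff_zero_is_identity(self):
        tree = self.build_supported_tree()
        assert to_newick(condense(tree, 0).root) == to_newick(tree.root)

    def test_root_to_leaf_depths_preserved(self):
        tree = self.build_supported_tree()
        condensed = condense(tree, 50)

        def depths(t):
            out = {}

            def walk(node, acc):
                if node.is_leaf():
                    out[node.name] = acc
                for c in node.children:
                    walk(c, acc + c.length)

            walk(t.root, 0.0)
            return out

        assert depths(condensed) == depths(tree)


class TestSimulationRecovery:
    def test_topology_recovery_at_long_sequences(self):
        generating = parse_newick(
            "((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05,(E:0.1,F:0.1):0.05);"
        )
        want = set(bipartitions(generating))
        hits = 0
        for seed in range(20):
            aln = simulate_alignment(generating, 2000, seed=seed)
            est = nj_tree(p_distance(aln))
            hits += set(bipartitions(est)) == want
        assert hits >= 19

    def test_zero_length_branches_give_identical_sequences(self):
        tree = parse_newick("(A:0,B:0,C:0);")
        aln = simulate_alignment(tree, 500, seed=3)
        assert len({s.residues for s in aln}) == 1

    def test_saturation_near_095(self):
        tree = parse_newick("(A:8,B:8,C:8);")
        aln = simulate_alignment(tree, 20000, seed=4)
        dm = p_distance(aln)
        off_diag = dm.matrix[np.triu_indices(3, 1)]
        assert np.all(np.abs(off_diag - 0.95) < 0.02)
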