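"""Poisson distances, NJ reconstruction, bootstrap, group assignment."""

import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from famscan.phylo import (
    AlignedProtein,
    DistanceMatrix,
    assign_groups,
    bootstrap_support,
    nj_tree,
    poisson_distance,
)
from famscan.records import ProteinRecord
from famscan.synth import SyntheticConfig, gen_group_alignment

_AA = "ACDEFGHIKLMNPQRSTVWY"


def random_additive_matrix(rng, n_taxa):
    """Distances summed along a random binary tree (truth topology)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=ns, rng=rng,
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = rng.uniform(0.05, 1.0)
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in ns]
    D = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(ns):
        for j, b in enumerate(ns):
            if i != j:
                D[i, j] = pdm.distance(a, b)
    tree.is_rooted = False
    return DistanceMatrix(labels, D), tree, ns


class TestPoissonDistance:
    def test_identical_rows_have_zero_distance(self):
        msa = [ProteinRecord("a", "MKVL"), ProteinRecord("b", "MKVL")]
        assert poisson_distance(msa).get("a", "b") == 0.0

    def test_one_difference_in_ten_sites(self):
        msa = [
            ProteinRecord("a", "MKVLMKVLMK"),
            ProteinRecord("b", "MKVLMKVLMA"),
        ]
        assert poisson_distance(msa).get("a", "b") == pytest.approx(
            -math.log(0.9)
        )

    def test_pairwise_deletion_of_gap_columns(self):
        msa = [
            AlignedProtein("a", "MKVL-KVLMK"),
            AlignedProtein("b", "MKVLM-VLMA"),
        ]
        # 8 comparable columns, 1 difference
        assert poisson_distance(msa).get("a", "b") == pytest.approx(
            -math.log(1 - 1 / 8)
        )

    def test_matches_brute_force_counter_on_random_alignment(self):
        rng = np.random.default_rng(17)
        msa = [
            ProteinRecord(f"r{i}", "".join(rng.choice(list(_AA), size=60)))
            for i in range(5)
        ]
        dm = poisson_distance(msa)
        for i in range(5):
            for j in range(i + 1, 5):
                diffs = sum(
                    a != b
                    for a, b in zip(msa[i].sequence, msa[j].sequence)
                )
                if diffs == 60:  # saturated: p = 1 has no finite distance
                    assert dm.get(f"r{i}", f"r{j}") == math.inf
                else:
                    assert dm.get(f"r{i}", f"r{j}") == pytest.approx(
                        -math.log(1 - diffs / 60)
                    )

    def test_all_gap_pair_is_an_error(self):
        msa = [
            AlignedProtein("a", "MK--"),
            AlignedProtein("b", "--VL"),
            AlignedProtein("c", "MKVL"),
        ]
        with pytest.raises(ValueError, match=r"\(a, b\)"):
            poisson_distance(msa)

    def test_saturated_pair_flagged(self):
        msa = [ProteinRecord("a", "MKVL"), ProteinRecord("b", "WYDE")]
        dm = poisson_distance(msa)
        assert frozenset(("a", "b")) in dm.saturated_pairs


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], D))
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_four_taxon_exact_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4))
        taxa = ["a", "b", "c", "d"]
        D = np.array(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 7.0, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(taxa, D))
        ns = tree.taxon_namespace
        truth = dendropy.Tree.get(
            data="((a:1,b:2):1,(c:3,d:4):0);", schema="newick",
            taxon_namespace=ns,
        )
        truth.is_rooted = False
        tree.encode_bipartitions()
        truth.encode_bipartitions()
        assert treecompare.symmetric_difference(tree, truth) == 0
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 1, "b": 2, "c": 3, "d": 4})

    @pytest.mark.parametrize("trial", range(50))
    def test_additive_matrices_reconstructed_exactly(self, trial):
        rng = np.random.default_rng(1000 + trial)

        import random as _random

        pyrng = _random.Random(int(rng.integers(2**31)))
        n_taxa = int(rng.integers(4, 9))
        dm, truth, ns = random_additive_matrix(pyrng, n_taxa)
        tree = nj_tree(dm)
        tree.migrate_taxon_namespace(ns)
        tree.encode_bipartitions()
        truth.encode_bipartitions()
        assert treecompare.symmetric_difference(tree, truth) == 0

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(4)
        n = 6
        M = rng.uniform(0.1, 1.0, size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = nj_tree(DistanceMatrix([f"t{i}" for i in range(n)], D))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1.0, 2.0], [1.5, 0, 1.0], [2.0, 1.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], D)


class TestBootstrap:
    def msa(self, seed=3):
        msa, _, _ = gen_group_alignment(
            SyntheticConfig(seed=seed), groups=("A", "B"), n_ref=3,
            n_query=0, length=240,
        )
        return msa

    def test_single_replicate_supports_are_zero_or_hundred(self):
        tree = bootstrap_support(self.msa(), n_reps=1, seed=0)
        supports = [
            int(n.label)
            for n in tree.preorder_internal_node_iter()
            if n.label is not None
        ]
        assert supports and all(s in (0, 100) for s in supports)

    def test_well_separated_clades_have_high_support(self):
        tree = bootstrap_support(self.msa(seed=3), n_reps=100, seed=3)
        bipartition_supports = {}
        all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        for node in tree.preorder_internal_node_iter():
            if node.label is None:
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            bipartition_supports[below] = int(node.label)
        clade_a = frozenset(l for l in all_leaves if l.startswith("A_"))
        support = bipartition_supports.get(
            clade_a, bipartition_supports.get(all_leaves - clade_a)
        )
        assert support is not None and support >= 95

    def test_fixed_seed_is_bit_reproducible(self, tmp_path):
        from famscan.io import write_newick

        t1 = bootstrap_support(self.msa(), n_reps=30, seed=7)
        t2 = bootstrap_support(self.msa(), n_reps=30, seed=7)
        p1, p2 = tmp_path / "a.nwk", tmp_path / "b.nwk"
        write_newick(t1, p1)
        write_newick(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_taxon_order_does_not_change_supports(self, tmp_path):
        from famscan.io import write_newick

        msa = self.msa(seed=5)
        t1 = bootstrap_support(msa, n_reps=25, seed=1)
        t2 = bootstrap_support(msa[::-1], n_reps=25, seed=1)
        p1, p2 = tmp_path / "a.nwk", tmp_path / "b.nwk"
        write_newick(t1, p1)
        write_newick(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestGroupAssignment:
    def test_query_sister_to_pure_pair(self):
        tree = dendropy.Tree.get(
            data="(((q:1,(r1:1,r2:1):1):1,(s1:1,s2:1):1):1,o1:1,o2:1);",
            schema="newick",
        )
        refs = {"r1": "III", "r2": "III", "s1": "I", "s2": "I",
                "o1": "II", "o2": "II"}
        assert assign_groups(tree, refs).groups["q"] == "III"

    def test_planted_groups_fully_recovered_seed5(self):
        msa, refs, truth = gen_group_alignment(SyntheticConfig(seed=5))
        tree = nj_tree(poisson_distance(msa))
        assignment = assign_groups(tree, refs)
        assert {k: assignment.groups[k] for k in truth} == truth

    def test_missing_reference_leaf_is_an_error(self):
        tree = dendropy.Tree.get(data="((a:1,b:1):1,c:1,d:1);",
                                 schema="newick")
        with pytest.raises(ValueError, match="ghost"):
            assign_groups(tree, {"a": "I", "ghost": "I"})

    def test_conflicting_smallest_clade_is_unplaced(self):
        tree = dendropy.Tree.get(
            data="(((q:1,r1:1):1,s1:1):1,(r2:1,s2:1):1,o:1);",
            schema="newick",
        )
        refs = {"r1": "I", "r2": "I", "s1": "II", "s2": "II"}
        assignment = assign_groups(tree, refs)
        # q's smallest informative clade is {q, r1} -> unanimous I
        assert assignment.groups["q"] == "I"
        # o sits outside both mixed clades; its smallest informative
        # side carries both groups -> unplaced
        assert assignment.groups["o"] == "unplaced"
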