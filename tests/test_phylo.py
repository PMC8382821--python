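import numpy as np
import pytest

from azamine.motif import MultipleAlignment
from azamine.phylo import (
    DistanceMatrix,
    PhyloTree,
    neighbor_joining,
    p_distance,
    robinson_foulds,
)
from _oracles import pdist_recount, random_additive_tree, rf_exhaustive
from conftest import random_protein


class TestPDistance:
    def make_msa(self, rows):
        return MultipleAlignment(ids=[f"r{i}" for i in range(len(rows))],
                                 rows=rows)

    def test_identical_rows_zero(self):
        msa = self.make_msa(["MKVLAW"] * 3)
        D = p_distance(msa)
        assert np.allclose(D.matrix, 0.0)

    def test_three_mismatches_in_hundred(self, rng):
        base = random_protein(rng, 100)
        mutated = "W" * 3 + base[3:] if not base.startswith("W") else \
            "Y" * 3 + base[3:]
        n_diff = sum(x != y for x, y in zip(base, mutated))
        msa = self.make_msa([base, mutated, base])
        D = p_distance(msa)
        assert D.matrix[0, 1] == pytest.approx(n_diff / 100)

    def test_gapped_columns_excluded_per_pair(self):
        msa = self.make_msa(["AC-G", "ACTG", "GCTG"])
        D = p_distance(msa)
        assert D.matrix[0, 1] == 0.0  # 3 comparable columns, all equal
        assert D.matrix[0, 2] == pytest.approx(1 / 3)
        assert D.matrix[1, 2] == pytest.approx(1 / 4)

    def test_matches_recount_oracle_on_random_gapped_msas(self, rng):
        for _ in range(25):
            n_rows = int(rng.integers(3, 8))
            n_cols = int(rng.integers(10, 40))
            rows = []
            for _ in range(n_rows):
                row = "".join(
                    "-" if rng.random() < 0.15 else random_protein(rng, 1)
                    for _ in range(n_cols)
                )
                if set(row) == {"-"}:
                    row = "A" + row[1:]
                rows.append(row)
            try:
                D = p_distance(self.make_msa(rows))
            except ValueError:
                continue  # a pair without comparable columns; oracle agrees
            assert np.allclose(D.matrix, pdist_recount(rows))

    def test_disjoint_gap_pair_rejected_by_name(self):
        msa = self.make_msa(["A--A", "A--A", "--G-"])
        # rows r0/r2 share no gap-free column? col0: A vs -, col2: - vs G...
        msa = self.make_msa(["AA--", "AA--", "--GG"])
        with pytest.raises(ValueError, match="r0.*r2"):
            p_distance(msa)

    def test_needs_three_rows(self):
        with pytest.raises(ValueError):
            p_distance(self.make_msa(["AC", "AC"]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(labels=["a", "b", "c"],
                           matrix=np.array([[0.0, 0.3, 0.5],
                                            [0.3, 0.0, 0.6],
                                            [0.5, 0.6, 0.0]]))
        tree = neighbor_joining(D)
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_five_taxon_additive_matrix_recovered(self, rng):
        newick, labels, mat = random_additive_tree(rng, 5)
        tree = neighbor_joining(DistanceMatrix(labels=labels, matrix=mat))
        assert rf_exhaustive(tree.to_newick(), newick) == 0
        # path lengths reproduce the additive input
        pdm = tree.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.tree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == \
                        pytest.approx(mat[i, j], abs=1e-9)

    def test_label_permutation_invariant_topology(self, rng):
        newick, labels, mat = random_additive_tree(rng, 7)
        perm = list(np.random.default_rng(3).permutation(len(labels)))
        shuffled = DistanceMatrix(
            labels=[labels[i] for i in perm],
            matrix=mat[np.ix_(perm, perm)],
        )
        t1 = neighbor_joining(DistanceMatrix(labels=labels, matrix=mat))
        t2 = neighbor_joining(shuffled)
        assert robinson_foulds(t1, t2) == (0, 0.0)

    def test_additive_recovery_across_sizes(self, rng):
        for n in (4, 6, 8, 10, 12):
            for _ in range(5):
                newick, labels, mat = random_additive_tree(rng, n)
                tree = neighbor_joining(
                    DistanceMatrix(labels=labels, matrix=mat)
                )
                assert rf_exhaustive(tree.to_newick(), newick) == 0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(labels=["a", "b"],
                                            matrix=np.zeros((2, 2))))

    def test_negative_lengths_clamped_and_flagged(self):
        # strongly non-additive matrix forces a negative NJ branch
        mat = np.array([
            [0.0, 0.1, 0.9, 0.9],
            [0.1, 0.0, 0.9, 0.1],
            [0.9, 0.9, 0.0, 0.9],
            [0.9, 0.1, 0.9, 0.0],
        ])
        tree = neighbor_joining(DistanceMatrix(labels=list("abcd"), matrix=mat))
        for node in tree.tree.preorder_node_iter():
            if node.edge.length is not None:
                assert node.edge.length >= 0.0
        assert tree.clamped_branches > 0
        assert tree.clamped


class TestDistanceMatrixValidation:
    def test_asymmetry_rejected(self):
        mat = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=["a", "b"], matrix=mat)

    def test_tsv_round_trip(self, tmp_path, rng):
        _, labels, mat = random_additive_tree(rng, 5)
        D = DistanceMatrix(labels=labels, matrix=mat)
        path = tmp_path / "d.tsv"
        D.to_tsv(path)
        back = DistanceMatrix.from_tsv(path)
        assert back.labels == labels
        assert np.allclose(back.matrix, mat, atol=1e-6)


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        t = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        assert robinson_foulds(t, t) == (0, 0.0)

    def test_distinct_four_taxon_topologies_maximal(self):
        t1 = PhyloTree.from_newick("((a:1,b:1):1,c:1,d:1);")
        t2 = PhyloTree.from_newick("((a:1,c:1):1,b:1,d:1);")
        assert robinson_foulds(t1, t2) == (2, 1.0)
        t3 = PhyloTree.from_newick("((a:1,d:1):1,b:1,c:1);")
        assert robinson_foulds(t1, t3) == (2, 1.0)
        assert robinson_foulds(t2, t3) == (2, 1.0)

    def test_symmetric_in_arguments(self, rng):
        n1, labels, _ = random_additive_tree(rng, 8)
        n2, _, _ = random_additive_tree(rng, 8)
        t1, t2 = PhyloTree.from_newick(n1), PhyloTree.from_newick(n2)
        assert robinson_foulds(t1, t2) == robinson_foulds(t2, t1)

    def test_matches_exhaustive_bipartition_oracle(self, rng):
        for n in (5, 6, 7, 8):
            for _ in range(5):
                n1, _, _ = random_additive_tree(rng, n)
                n2, _, _ = random_additive_tree(rng, n)
                t1, t2 = PhyloTree.from_newick(n1), PhyloTree.from_newick(n2)
                rf, norm = robinson_foulds(t1, t2)
                assert rf == rf_exhaustive(n1, n2)
                assert norm == pytest.approx(rf / (2 * (n - 3)))
                # zero iff identical bipartition sets
                assert (rf == 0) == (rf_exhaustive(n1, n2) == 0)

    def test_leaf_mismatch_reports_difference(self):
        t1 = PhyloTree.from_newick("((a:1,b:1):1,c:1,d:1);")
        t2 = PhyloTree.from_newick("((a:1,b:1):1,c:1,e:1);")
        with pytest.raises(ValueError, match="d.*e"):
            robinson_foulds(t1, t2)

    def test_newick_round_trip_preserves_topology_and_lengths(self, rng):
        newick, labels, mat = random_additive_tree(rng, 9)
        tree = neighbor_joining(DistanceMatrix(labels=labels, matrix=mat))
        back = PhyloTree.from_newick(tree.to_newick())
        assert robinson_foulds(tree, back) == (0, 0.0)
        total1 = sum(e.length for e in tree.tree.preorder_edge_iter()
                     if e.length)
        total2 = sum(e.length for e in back.tree.preorder_edge_iter()
                     if e.length)
        assert total2 == pytest.approx(total1, abs=1e-6)
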