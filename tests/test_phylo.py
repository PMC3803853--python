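import math
from types import SimpleNamespace

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from eyevolve.phylo import (DistanceMatrix, distances_from_sequences,
                            has_cherry, leaf_distance, neighbor_joining,
                            pairwise_distance, to_newick, trim_to_hit)
from eyevolve.simulate import random_protein, reverse_translate

from .oracles import random_additive_tree


class TestTrim:
    def test_full_length_hit_returns_whole_translation(self, rng):
        prot = random_protein(40, rng)
        dna = reverse_translate(prot, rng)
        hit = SimpleNamespace(frame=1, qstart=1, qend=len(dna))
        assert trim_to_hit(dna, hit) == prot

    def test_codons_five_to_ten_give_six_residues(self, rng):
        prot = random_protein(40, rng)
        dna = reverse_translate(prot, rng)
        hit = SimpleNamespace(frame=1, qstart=13, qend=30)
        assert trim_to_hit(dna, hit) == prot[4:10]

    def test_misaligned_interval_fails(self, rng):
        dna = reverse_translate(random_protein(40, rng), rng)
        with pytest.raises(ValueError):
            trim_to_hit(dna, SimpleNamespace(frame=1, qstart=2, qend=30))


class TestPairwiseDistance:
    def test_identical_sequences_are_at_distance_zero(self):
        assert pairwise_distance("MKV", "MKV", kimura=False) == 0.0
        assert pairwise_distance("MKV", "MKV", kimura=True) == 0.0

    @pytest.mark.parametrize("d,expected", [(0.1, 0.10758), (0.5, 0.79851)])
    def test_kimura_correction_formula(self, d, expected):
        n = 100
        a = "A" * n
        b = "C" * int(d * n) + "A" * (n - int(d * n))
        assert pairwise_distance(a, b, kimura=True) == \
            pytest.approx(expected, abs=1e-5)

    def test_gap_columns_are_excluded(self):
        assert pairwise_distance("MK-V", "MKWV", kimura=False) == 0.0

    def test_saturation_and_empty_comparisons_fail(self):
        with pytest.raises(ValueError, match="Kimura"):
            pairwise_distance("A" * 10, "C" * 10, kimura=True)
        with pytest.raises(ValueError, match="gap-free"):
            pairwise_distance("--", "AA", kimura=False)


class TestDistanceMatrix:
    def test_rejects_asymmetric_or_negative(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0.0]]))

    def test_phylip_output_shape(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 1.5], [1.5, 0.0]]))
        lines = dm.to_phylip().strip().split("\n")
        assert lines[0] == "2"
        assert lines[1].split()[0] == "a"
        assert float(lines[1].split()[-1]) == 1.5


class TestNeighborJoining:
    def test_three_leaf_two_point_formulas(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        tree = neighbor_joining(dm)
        assert leaf_distance(tree, "A", "B") == pytest.approx(2.0)
        assert leaf_distance(tree, "A", "C") == pytest.approx(4.0)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_leaf_to_itself_and_unknown_leaf(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        tree = neighbor_joining(dm)
        assert leaf_distance(tree, "B", "B") == 0.0
        with pytest.raises(KeyError):
            leaf_distance(tree, "A", "Z")

    def test_fewer_than_three_leaves_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"],
                                            np.array([[0, 1], [1, 0.0]])))

    def test_recovers_random_additive_trees_exactly(self, rng):
        """On additive matrices NJ must reproduce the generating topology and
        every patristic distance (to 1e-9)."""
        for _ in range(20):
            n = int(rng.integers(4, 9))
            labels, dist, _ = random_additive_tree(n, rng)
            tree = neighbor_joining(DistanceMatrix(labels, dist))
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.taxon_namespace}
            for i in range(n):
                for j in range(i + 1, n):
                    got = pdm.patristic_distance(taxa[labels[i]],
                                                 taxa[labels[j]])
                    assert got == pytest.approx(dist[i, j], abs=1e-9)

    def test_equidistant_matrix_resolved_deterministically(self):
        dm = DistanceMatrix(["a", "b", "c", "d"],
                            np.full((4, 4), 2.0) - 2.0 * np.eye(4))
        t1 = to_newick(neighbor_joining(dm))
        t2 = to_newick(neighbor_joining(dm))
        assert t1 == t2


def test_distances_from_sequences_and_cherry_detection(rng):
    base = random_protein(80, rng)
    from eyevolve.simulate import evolve_protein
    seqs = {
        "h": base,
        "ch": evolve_protein(base, 0.1, rng),
        "f": evolve_protein(base, 0.5, rng),
    }
    seqs["cf"] = evolve_protein(seqs["f"], 0.1, rng)
    dm = distances_from_sequences(seqs)
    assert dm.get("h", "ch") < dm.get("h", "f")
    tree = neighbor_joining(dm)
    assert has_cherry(tree, "h", "ch")
    assert has_cherry(tree, "f", "cf")
    assert not has_cherry(tree, "h", "cf")
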