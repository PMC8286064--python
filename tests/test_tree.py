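"""Alignment, distances, neighbor joining and family similarity trees."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from irpkit import simulate as sim
from irpkit.tree import (DistanceMatrix, distance, family_tree, leaf_distances,
                         neighbor_joining, pairwise_align, splits)

from oracles import enumerate_global_score, random_additive_tree

BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestPairwiseAlign:
    def test_self_alignment_score(self):
        score, rows = pairwise_align("MKR", "MKR")
        expected = sum(BLOSUM62[aa, aa] for aa in "MKR")
        assert score == expected and rows == ("MKR", "MKR")

    def test_single_gap_score(self):
        # oracle: exhaustive enumeration of all alignments of MKR vs MR
        score, _rows = pairwise_align("MKR", "MR")
        assert score == enumerate_global_score("MKR", "MR")
        assert score == BLOSUM62["M", "M"] + BLOSUM62["R", "R"] - 12

    def test_symmetry_on_random_8mers(self):
        rng = np.random.default_rng(3)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(rng.choice(list(aas), 8))
            b = "".join(rng.choice(list(aas), 8))
            assert pairwise_align(a, b)[0] == pairwise_align(b, a)[0]

    def test_invalid_character_errors(self):
        with pytest.raises(ValueError):
            pairwise_align("MK1", "MK")

    def test_enumeration_oracle_short_sequences(self):
        """Scores equal brute-force enumeration over a 4-letter alphabet:
        all pairs up to length 2 exhaustively, longer pairs sampled."""
        alphabet = "ACDE"
        short = [
            "".join(s) for n in (1, 2)
            for s in itertools.product(alphabet, repeat=n)
        ]
        for a, b in itertools.combinations_with_replacement(short, 2):
            assert pairwise_align(a, b)[0] == enumerate_global_score(a, b), (a, b)
        rng = np.random.default_rng(17)
        for _ in range(60):
            a = "".join(rng.choice(list(alphabet), rng.integers(3, 7)))
            b = "".join(rng.choice(list(alphabet), rng.integers(3, 7)))
            assert pairwise_align(a, b)[0] == enumerate_global_score(a, b), (a, b)


class TestDistance:
    def test_identical_sequences_zero(self):
        rows = ("MKR", "MKR")
        assert distance(rows, "p") == 0.0
        assert distance(rows, "poisson") == 0.0

    def test_poisson_closed_form(self):
        rows = ("AAAA", "AAGG")
        assert distance(rows, "p") == pytest.approx(0.5)
        assert distance(rows, "poisson") == pytest.approx(-np.log(0.5))

    def test_all_mismatch_capped(self):
        rows = ("AAAA", "GGGG")
        assert distance(rows, "poisson") == 5.0

    def test_no_aligned_columns_errors(self):
        with pytest.raises(ValueError):
            distance(("AA--", "--GG"), "p")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        tree = neighbor_joining(dm)
        lengths = {leaf.label: leaf.length for leaf in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_four_taxon_exact(self):
        # tree: (A:1,B:2):1 joined to (C:3,D:4)
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0.0]])
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C", "D"), d))
        got = leaf_distances(tree)
        for (x, y), expected in {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
                                 ("B", "C"): 6, ("B", "D"): 7,
                                 ("C", "D"): 7}.items():
            assert got[(x, y)] == pytest.approx(expected)
        assert splits(tree) == {frozenset({"A", "B"})}

    def test_fewer_than_three_errors(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("A", "B"),
                                            np.array([[0, 1], [1, 0.0]])))

    def test_asymmetric_matrix_errors(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))

    def test_tie_break_deterministic(self):
        d = np.array([[0, 1, 1, 1],
                      [1, 0, 1, 1],
                      [1, 1, 0, 1],
                      [1, 1, 1, 0.0]])
        dm = DistanceMatrix(("A", "B", "C", "D"), d)
        first = neighbor_joining(dm)
        second = neighbor_joining(dm)
        from irpkit.io import write_newick
        assert write_newick(first) == write_newick(second)

    def test_recovers_200_random_additive_trees(self):
        """NJ topology and path lengths match 200 random 6-leaf trees."""
        rng = np.random.default_rng(1234)
        for trial in range(200):
            leaves, dmat, true_splits = random_additive_tree(rng, 6)
            d = np.array([[dmat[(a, b)] for b in leaves] for a in leaves])
            tree = neighbor_joining(DistanceMatrix(tuple(leaves), d))
            assert splits(tree) == true_splits, trial
            got = leaf_distances(tree)
            for a, b in itertools.combinations(leaves, 2):
                assert got[tuple(sorted((a, b)))] == pytest.approx(
                    dmat[(a, b)]), trial

    def test_agrees_with_scikit_bio(self):
        """Independent cross-check against the scikit-bio NJ implementation."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        leaves, dmat, _true = random_additive_tree(rng, 7)
        d = np.array([[dmat[(a, b)] for b in leaves] for a in leaves])
        d = (d + d.T) / 2  # exact symmetry (path sums differ by float eps)
        mine = neighbor_joining(DistanceMatrix(tuple(leaves), d))
        theirs = skbio_nj(SkbioDM(d, ids=leaves))
        their_splits = set()
        all_leaves = frozenset(leaves)
        for node in theirs.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < len(leaves) - 1:
                comp = all_leaves - below
                side = below if (len(below), sorted(below)) <= \
                    (len(comp), sorted(comp)) else comp
                their_splits.add(side)
        assert splits(mine) == their_splits


@pytest.fixture(scope="module")
def batch_tree():
    records = sim.fixture_batch(seed=8, n_per_family=10, noise_rate=0.05)
    return records, family_tree(records)


class TestFamilyTree:

    def test_multinsulins_group_with_dilp7(self, batch_tree):
        """Multinsulin leaves are nearer dilp7 leaves than any other family."""
        _records, tree = batch_tree
        dists = leaf_distances(tree)

        def mean_between(fam_a, fam_b):
            pairs = [v for (x, y), v in dists.items()
                     if {x.split("_")[0], y.split("_")[0]} == {fam_a, fam_b}]
            return float(np.mean(pairs))

        to_dilp7 = mean_between("multinsulin", "dilp7")
        assert to_dilp7 < mean_between("multinsulin", "IGF")
        assert to_dilp7 < mean_between("multinsulin", "GSS")
        assert to_dilp7 < mean_between("multinsulin", "octinsulin")

    def test_gss_nearer_igf_than_dilp7(self, batch_tree):
        _records, tree = batch_tree
        dists = leaf_distances(tree)

        def mean_between(fam_a, fam_b):
            pairs = [v for (x, y), v in dists.items()
                     if {x.split("_")[0], y.split("_")[0]} == {fam_a, fam_b}]
            return float(np.mean(pairs))

        assert mean_between("GSS", "IGF") < mean_between("GSS", "dilp7")

    def test_deterministic(self):
        from irpkit.io import write_newick
        records = sim.fixture_batch(seed=9, n_per_family=3, noise_rate=0.02)
        assert write_newick(family_tree(records)) == \
               write_newick(family_tree(records))

    def test_too_few_records_errors(self):
        records = sim.fixture_batch(seed=9, n_per_family=1, noise_rate=0.0)[:2]
        with pytest.raises(ValueError):
            family_tree(records)

    def test_frameworkless_record_excluded_with_warning(self, caplog):
        import logging

        records = sim.fixture_batch(seed=10, n_per_family=1, noise_rate=0.0)
        decoy = sim.make_precursor("GSS", 99, ablate="core-cys")
        with caplog.at_level(logging.WARNING, logger="irpkit"):
            tree = family_tree(records + [decoy])
        labels = {l.label for l in tree.leaves()}
        assert decoy.id not in labels
        assert any("framework" in r.message for r in caplog.records)
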