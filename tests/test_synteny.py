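"""Microsynteny clustering, conserved arrangements, species comparison."""

import numpy as np
import pytest

from irpkit import simulate as sim
from irpkit.io import GeneLocus
from irpkit.synteny import (cluster_loci, compare_layouts,
                            conserved_arrangement_check)


def _locus(gene_id, label, region, start, end, strand="+"):
    return GeneLocus(gene_id, label, region, start, end, strand)


class TestClusterLoci:
    def test_cluster_plus_distant_singleton(self):
        """Four loci 20 kb apart plus one 6 Mb away at a 1 Mb threshold."""
        loci, pos = [], 0
        for i, label in enumerate(["octinsulin", "IGF", "IGF", "dilp7"]):
            loci.append(_locus(f"g{i}", label, "chr1", pos, pos + 5_000))
            pos += 5_000 + 20_000
        loci.append(_locus("gss", "GSS", "chr1", pos + 6_000_000,
                           pos + 6_005_000))
        clusters = cluster_loci(loci, 1_000_000)
        assert sorted(len(c.members) for c in clusters) == [1, 4]

    def test_all_scattered_gives_singletons(self):
        loci = [_locus(f"g{i}", "IGF", f"s{i}", 100, 200) for i in range(5)]
        clusters = cluster_loci(loci, 1_000_000)
        assert [len(c.members) for c in clusters] == [1] * 5

    def test_infinite_gap_one_cluster_per_region(self):
        loci = [_locus("a", "IGF", "chr1", 0, 10),
                _locus("b", "GSS", "chr1", 10**9, 10**9 + 10),
                _locus("c", "dilp7", "chr2", 5, 15)]
        clusters = cluster_loci(loci, 10**15)
        assert sorted(len(c.members) for c in clusters) == [1, 2]

    def test_partition_property(self):
        rng = np.random.default_rng(7)
        loci = []
        for i in range(40):
            start = int(rng.integers(0, 10**7))
            loci.append(_locus(f"g{i}", "IGF", f"chr{int(rng.integers(3))}",
                               start, start + int(rng.integers(1, 10_000))))
        clusters = cluster_loci(loci, 50_000)
        clustered = [m.gene_id for c in clusters for m in c.members]
        assert sorted(clustered) == sorted(l.gene_id for l in loci)

    def test_monotonicity_in_max_gap(self):
        rng = np.random.default_rng(11)
        loci = []
        for i in range(30):
            start = int(rng.integers(0, 10**6))
            loci.append(_locus(f"g{i}", "GSS", "chr1", start,
                               start + int(rng.integers(1, 5_000))))
        counts = [len(cluster_loci(loci, gap))
                  for gap in (1_000, 10_000, 100_000, 1_000_000)]
        assert counts == sorted(counts, reverse=True)

    def test_gaps_equal_direct_subtraction(self):
        loci = [_locus("a", "IGF", "chr1", 0, 1_000),
                _locus("b", "GSS", "chr1", 21_000, 30_000),
                _locus("c", "dilp7", "chr1", 30_500, 31_000)]
        (cluster,) = cluster_loci(loci, 10**6)
        assert cluster.gaps_kb == (20.0, 0.5)

    def test_overlapping_loci_gap_zero(self):
        loci = [_locus("a", "IGF", "chr1", 0, 1_000),
                _locus("b", "IGF", "chr1", 500, 2_000)]
        (cluster,) = cluster_loci(loci, 10**6)
        assert cluster.gaps_kb == (0.0,)


class TestConservedArrangement:
    def _cluster(self, labels):
        loci = [_locus(f"g{i}", label, "chr1", i * 10_000, i * 10_000 + 1_000)
                for i, label in enumerate(labels)]
        (cluster,) = cluster_loci(loci, 10**6)
        return cluster

    def test_igf_in_the_middle(self):
        cluster = self._cluster(["octinsulin", "IGF", "dilp7"])
        assert conserved_arrangement_check(cluster) == "triplet_with_IGF_middle"

    def test_igf_first_is_other(self):
        cluster = self._cluster(["IGF", "octinsulin", "dilp7"])
        assert conserved_arrangement_check(cluster) == "other"

    def test_missing_dilp7_is_other(self):
        cluster = self._cluster(["octinsulin", "IGF", "GSS"])
        assert conserved_arrangement_check(cluster) == "other"

    def test_gonadulin_label_counts_as_octinsulin(self):
        cluster = self._cluster(["gonadulin", "IGF", "IGF", "dilp7"])
        assert conserved_arrangement_check(cluster) == "triplet_with_IGF_middle"


class TestCompareLayouts:
    def test_identical_compositions_shared(self):
        a = cluster_loci(sim.make_synteny_layout("echinozoa_clustered", 1))
        b = cluster_loci(sim.make_synteny_layout("echinozoa_clustered", 2))
        table = compare_layouts({"spA": a, "spB": b})
        shared = table[table.verdict == "shared"]
        assert "IGF+IGF+dilp7+octinsulin" in set(shared.composition)

    def test_clustered_vs_scattered_mostly_different(self):
        a = cluster_loci(sim.make_synteny_layout("echinozoa_clustered", 1))
        b = cluster_loci(sim.make_synteny_layout("asterozoa_scattered", 1))
        table = compare_layouts({"clustered": a, "scattered": b})
        multi = table[table.composition.str.contains(r"\+")]
        assert (multi.verdict == "different").all()

    def test_single_species_errors(self):
        a = cluster_loci(sim.make_synteny_layout("echinozoa_clustered", 1))
        with pytest.raises(ValueError, match="2 species"):
            compare_layouts({"only": a})


class TestGeneratorLayouts:
    def test_clustered_layout_structure(self):
        loci = sim.make_synteny_layout("echinozoa_clustered", 5)
        clusters = cluster_loci(loci, 1_000_000)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 4]
        big = max(clusters, key=lambda c: len(c.members))
        assert conserved_arrangement_check(big) == "triplet_with_IGF_middle"
        assert all(20.0 <= g <= 50.0 for g in big.gaps_kb)

    def test_scattered_layout_all_singletons(self):
        loci = sim.make_synteny_layout("asterozoa_scattered", 5)
        clusters = cluster_loci(loci, 1_000_000)
        assert all(len(c.members) == 1 for c in clusters)

    def test_gss_gap_is_six_megabases(self):
        loci = sim.make_synteny_layout("echinozoa_clustered", 5)
        by_id = {l.gene_id: l for l in loci}
        assert by_id["gss1"].start - by_id["dilp7_1"].end == 6_000_000
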