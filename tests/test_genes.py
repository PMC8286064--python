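"""Intron phases, domain mapping and gene-structure signatures."""

import numpy as np
import pytest

from irpkit import simulate as sim
from irpkit.genes import (IncompleteCdsError, compute_intron_phases,
                          gene_signature, map_introns_to_domains)
from irpkit.io import GeneModel
from irpkit.pipeline import annotate_record

from oracles import codon_walk_phases


def _model_from_lengths(lengths, strand="+", gap=100):
    exons, pos = [], 0
    for length in lengths:
        exons.append((pos, pos + length))
        pos += length + gap
    if strand == "-":
        # mirror the whole gene; transcript order (and lengths) are preserved
        span = pos
        exons = [(span - e, span - s) for s, e in exons]
    return GeneModel("g.t1", "chr1", strand, tuple(exons))


class TestComputeIntronPhases:
    @pytest.mark.parametrize("lengths,phases", [
        ((10, 20), [1]),
        ((9, 12, 21), [0, 0]),
        ((8, 9, 10), [2, 2]),
    ])
    def test_known_exon_partitions(self, lengths, phases):
        introns = compute_intron_phases(_model_from_lengths(lengths))
        assert [i.phase for i in introns] == phases
        assert [i.cds_offset for i in introns] == \
               list(np.cumsum(lengths)[:-1])

    def test_single_exon_no_introns(self):
        assert compute_intron_phases(_model_from_lengths((21,))) == []

    def test_incomplete_cds_errors(self):
        with pytest.raises(IncompleteCdsError):
            compute_intron_phases(_model_from_lengths((10, 12)))

    def test_codon_walk_oracle_on_random_partitions(self):
        """Phases equal the nucleotide-walking oracle for 1,000 partitions."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n_exons = int(rng.integers(2, 6))
            lengths = [int(rng.integers(1, 200)) for _ in range(n_exons - 1)]
            total = sum(lengths)
            last = 3 * int(rng.integers(max(1, total // 3 + 1), total + 100)) - total
            if last <= 0:
                last += 3 * ((-last) // 3 + 1)
            lengths.append(last)
            model = _model_from_lengths(tuple(lengths))
            got = [i.phase for i in compute_intron_phases(model)]
            expected = codon_walk_phases(["N" * l for l in lengths])
            assert got == expected

    def test_strand_flip_invariance(self):
        lengths = (8, 9, 10)
        plus = compute_intron_phases(_model_from_lengths(lengths, "+"))
        minus = compute_intron_phases(_model_from_lengths(lengths, "-"))
        assert [i.phase for i in plus] == [i.phase for i in minus]
        assert [i.cds_offset for i in plus] == [i.cds_offset for i in minus]

    @pytest.mark.parametrize("family", sim.FAMILIES)
    def test_generator_genes_match_oracle(self, family):
        gene = sim.make_gene_model(family, 5)
        got = [i.phase for i in compute_intron_phases(gene.model)]
        exon_seqs = [gene.cds[sum(gene.model.exon_lengths[:i]):
                              sum(gene.model.exon_lengths[:i + 1])]
                     for i in range(len(gene.model.cds_exons))]
        assert got == codon_walk_phases(exon_seqs)


class TestDomainMapping:
    def test_gss_intron_lands_in_c_domain(self):
        gene = sim.make_gene_model("GSS", 3)
        res = annotate_record(gene.protein)
        introns = map_introns_to_domains(
            compute_intron_phases(gene.model), res.annotation,
            gene.model.cds_length, len(gene.protein.residues))
        assert [(i.phase, i.domain_tag) for i in introns] == [(1, "C")]

    def test_intron_in_a_domain_tagged_a(self):
        gene = sim.make_gene_model("GSS", 3)
        res = annotate_record(gene.protein)
        a_start = res.annotation.intervals["A"][0]
        cds_len = gene.model.cds_length
        cut = 3 * (a_start + 2)
        model = _model_from_lengths((cut, cds_len - cut))
        introns = map_introns_to_domains(
            compute_intron_phases(model), res.annotation,
            cds_len, len(gene.protein.residues))
        assert introns[0].domain_tag == "A"

    def test_length_mismatch_errors_naming_both(self):
        gene = sim.make_gene_model("GSS", 3)
        res = annotate_record(gene.protein)
        with pytest.raises(ValueError, match=r"\d+"):
            map_introns_to_domains(
                compute_intron_phases(gene.model), res.annotation,
                gene.model.cds_length, len(gene.protein.residues) + 7)


class TestGeneSignature:
    @pytest.mark.parametrize("family,token", [
        ("GSS", "GSS_or_octinsulin"),
        ("octinsulin", "GSS_or_octinsulin"),
        ("dilp7", "dilp7"),
        ("multinsulin", "multinsulin"),
        ("IGF", "IGF"),
    ])
    def test_generator_family_tokens(self, family, token):
        gene = sim.make_gene_model(family, 9)
        res = annotate_record(gene.protein)
        introns = map_introns_to_domains(
            compute_intron_phases(gene.model), res.annotation,
            gene.model.cds_length, len(gene.protein.residues))
        assert gene_signature(introns, gene.model.cds_length).token == token

    def test_no_phase1_in_c_is_unknown(self):
        gene = sim.make_gene_model("GSS", 9)
        res = annotate_record(gene.protein)
        cds_len = gene.model.cds_length
        model = _model_from_lengths((30, cds_len - 30))  # phase-0 intron in B
        introns = map_introns_to_domains(
            compute_intron_phases(model), res.annotation,
            cds_len, len(gene.protein.residues))
        sig = gene_signature(introns, cds_len)
        assert sig.token == "unknown" and sig.matched_rules == ()


class TestGeneratorGeneModels:
    @pytest.mark.parametrize("family,n_exons", [
        ("GSS", 2), ("octinsulin", 2), ("IGF", 3), ("dilp7", 3),
        ("multinsulin", 4),
    ])
    def test_exon_counts(self, family, n_exons):
        gene = sim.make_gene_model(family, 1)
        assert len(gene.model.cds_exons) == n_exons

    @pytest.mark.parametrize("family", sim.FAMILIES)
    def test_cds_translates_to_precursor(self, family):
        from Bio.Seq import Seq

        gene = sim.make_gene_model(family, 4)
        assert str(Seq(gene.cds).translate()) == gene.protein.residues + "*"
        # the genomic exons spliced together reconstruct the CDS
        genomic = sorted(gene.model.cds_exons)
        spliced = "".join(gene.genome[s:e] for s, e in genomic)
        assert spliced == gene.cds
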