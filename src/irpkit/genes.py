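"""Intron phases, intron-to-domain mapping, and family gene-structure signatures.

All irp genes share a phase-1 intron in the conceptual C domain - the only
coding intron of the GSS and octinsulin genes.  dilp7-ortholog and multinsulin
genes share an additional phase-2 intron, multinsulin genes yet another phase-1
intron, and IGF genes carry a phase-0 intron near the end of the coding
sequence.  These signatures are family-diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .config import Config
from .domains import DomainAnnotation
from .io import GeneModel

__all__ = ["IntronRecord", "GeneSignature", "IncompleteCdsError",
           "compute_intron_phases", "map_introns_to_domains", "gene_signature"]


class IncompleteCdsError(ValueError):
    pass


@dataclass(frozen=True)
class IntronRecord:
    index: int           # ordinal in transcript, 0-based
    cds_offset: int      # coding nucleotides upstream of the intron
    phase: int           # cds_offset mod 3
    aa_pos: int          # cds_offset div 3 (the codon the intron interrupts)
    domain_tag: str | None = None

    def __post_init__(self) -> None:
        if self.phase != self.cds_offset % 3:
            raise ValueError("phase must equal cds_offset mod 3")


@dataclass(frozen=True)
class GeneSignature:
    token: str                       # IGF | GSS_or_octinsulin | dilp7 | multinsulin | unknown
    matched_rules: tuple[str, ...] = ()


def compute_intron_phases(gene: GeneModel) -> list[IntronRecord]:
    """Phase of each intron from cumulative exon lengths in transcript order."""
    if not gene.complete:
        raise IncompleteCdsError(
            f"{gene.gene_id}: CDS length {gene.cds_length} not divisible by 3")
    introns: list[IntronRecord] = []
    offset = 0
    for i, length in enumerate(gene.exon_lengths[:-1]):
        offset += length
        introns.append(IntronRecord(
            index=i, cds_offset=offset, phase=offset % 3, aa_pos=offset // 3))
    return introns


def map_introns_to_domains(introns: list[IntronRecord],
                           annotation: DomainAnnotation,
                           cds_length: int,
                           protein_length: int) -> list[IntronRecord]:
    """Fill each intron's domain tag from the protein domain intervals.

    The CDS must correspond to the protein: ``cds/3 - 1 == protein length``
    (with stop codon) or ``cds/3 == protein length`` (without).
    """
    aa_from_cds = cds_length // 3
    if aa_from_cds not in (protein_length, protein_length + 1):
        raise ValueError(
            f"CDS/protein length mismatch: CDS {cds_length} nt codes for "
            f"{aa_from_cds} residues, protein has {protein_length}")
    signal_end = annotation.intervals.get("signal", (0, 0))[1]
    mapped = []
    for intron in introns:
        if intron.aa_pos < signal_end:
            tag = "signal"
        else:
            tag = annotation.domain_at(min(intron.aa_pos, protein_length - 1))
        mapped.append(replace(intron, domain_tag=tag))
    return mapped


def gene_signature(introns: list[IntronRecord], cds_length: int,
                   config: Config | None = None) -> GeneSignature:
    """Family token from the intron phase/placement pattern.

    A phase-1 intron in the C domain is required for any non-unknown token;
    a phase-2 intron plus a second phase-1 intron marks multinsulin; a phase-2
    intron alone dilp7; a late phase-0 intron IGF; the bare phase-1-in-C
    pattern is shared by GSS and octinsulin.
    """
    cfg = config or Config()
    p1_in_c = [i for i in introns if i.phase == 1 and i.domain_tag == "C"]
    if not p1_in_c:
        return GeneSignature("unknown")
    rules = ["phase1-in-C"]
    others = [i for i in introns if i not in p1_in_c]
    has_p2 = any(i.phase == 2 for i in others)
    extra_p1 = any(i.phase == 1 for i in others)
    late_cut = (1.0 - cfg["genes.igf_terminal_frac"]) * cds_length
    late_p0 = any(i.phase == 0 and i.cds_offset >= late_cut for i in others)
    unmatched = [
        i for i in others
        if not (i.phase == 2 or i.phase == 1
                or (i.phase == 0 and i.cds_offset >= late_cut))
    ]
    if unmatched:
        return GeneSignature("unknown")
    if has_p2 and extra_p1:
        return GeneSignature("multinsulin",
                             tuple(rules + ["phase2", "extra-phase1"]))
    if has_p2:
        return GeneSignature("dilp7", tuple(rules + ["phase2"]))
    if late_p0:
        return GeneSignature("IGF", tuple(rules + ["late-phase0"]))
    if not others:
        return GeneSignature("GSS_or_octinsulin", tuple(rules + ["only-intron"]))
    return GeneSignature("unknown")
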