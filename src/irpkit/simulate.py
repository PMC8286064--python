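"""Deterministic generator of family-templated irp precursors, gene models,
synteny layouts and receptor presets.

Each of the five families is instantiated from a hand-built template that
carries the family's defining marks: the six-cysteine core (human-insulin
modal spacings 12/3/8), planted convertase sites in clean contexts, the
octinsulin extra cysteine pair (B-start + post-CA4), the multinsulin extra
pair (C domain), the dilp7 F domain, the IGF charged D+E tail with a weak
furin site, and the family intron plan (phase-1 in C everywhere; phase-2
shared by dilp7/multinsulin; an extra phase-1 in B for multinsulin, which
therefore has four coding exons; a late phase-0 intron for IGF).

Point-mutation noise never touches the defining marks (core and extra
cysteines, planted site motifs and their acceptance contexts, the signal
c-region): noise tests the robustness of thresholds, not the destruction of
the marks.  Everything is a pure function of (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq

from .io import GeneLocus, GeneModel, SequenceRecord
from .scales import AMINO_ACIDS

__all__ = ["FamilyTemplate", "SyntheticGene", "FAMILIES", "GENERATOR_VERSION",
           "template", "make_precursor", "make_gene_model",
           "make_synteny_layout", "make_receptor", "fixture_batch"]

GENERATOR_VERSION = "1"

FAMILIES = ("IGF", "GSS", "octinsulin", "dilp7", "multinsulin")

_FAMILY_CODE = {name: i + 1 for i, name in enumerate(FAMILIES)}

#: signal peptide with a hydrophobic h-region and small residues at -3/-1
SIGNAL = "MKTLLILAVLAAASA"                       # cleavage after residue 15

#: Family-specific B-chain interiors (CB1 + 11 residues + CB2) and A-chain
#: cores (CC + 3 + C + 8 + C).  The interiors encode the lineage structure of
#: the superfamily: GSS cores resemble IGF (from which GSS arose), multinsulin
#: cores resemble dilp7 (its parent lineage), octinsulin stands apart.  All
#: variants keep the modal human-insulin spacings 12 / 3 / 8 and contain no
#: C/K/R/P that could fake a framework or cleavage context.
_B_VAR = {
    "IGF": "GSHLVEALYLV",
    "GSS": "GSHLVEALYMV",
    "octinsulin": "ASQNVGDMYEV",
    "dilp7": "DTHNVESLWSV",
    "multinsulin": "DTHNVESLWAV",
}
_A_VAR = {
    "IGF": ("TSI", "SLYQLENY"),
    "GSS": ("TGI", "SLYQMENY"),
    "octinsulin": ("QEG", "AHNDMSWG"),
    "dilp7": ("NTD", "GMDEWTHF"),
    "multinsulin": ("NTD", "GMDEWTHY"),
}

B_CORE_LEN = 13                                   # CB1 .. CB2, 12 apart
A_CORE_LEN = 15                                   # CA1 CA2 x3 CA3 x8 CA4


def _b_core(family: str) -> str:
    return "C" + _B_VAR[family] + "C"


def _a_core(family: str) -> str:
    x3, x8 = _A_VAR[family]
    return "CC" + x3 + "C" + x8 + "C"


_DIBASIC = "KR"
_SPACER = "GIVE"                                  # pro-insulin-style A lead-in


@dataclass(frozen=True)
class FamilyTemplate:
    """A noise-free family instance with full ground truth."""

    name: str
    sequence: str
    signal_end: int
    core_cys: tuple[int, ...]                     # cb1, cb2, ca1, ca2, ca3, ca4
    extra_cys: tuple[int, ...]
    dibasic_sites: tuple[int, ...]                # P1 indices of planted KR sites
    furin_sites: tuple[int, ...]                  # P1 indices of planted furin sites
    domains: dict[str, tuple[int, int]]           # ground-truth intervals
    intron_plan: tuple[tuple[int, int], ...]      # (aa_pos, phase) pairs
    protected: frozenset[int]                     # mutation-ineligible positions

    @property
    def mature_start(self) -> int:
        return self.signal_end


def _assemble(name: str, pieces: list[tuple[str, str]],
              intron_plan: list[tuple[int, int]]) -> FamilyTemplate:
    """Build a template from (tag, segment) pieces with automatic bookkeeping."""
    seq = ""
    spans: dict[str, tuple[int, int]] = {}
    for tag, segment in pieces:
        start = len(seq)
        seq += segment
        if tag in spans:  # extend an already-open domain (e.g. split B pieces)
            spans[tag] = (spans[tag][0], len(seq))
        else:
            spans[tag] = (start, len(seq))

    # core cysteines: the B-core termini and the four A-core positions
    b_start = seq.index(_b_core(name))
    a_start = seq.index(_a_core(name))
    core = (b_start, b_start + B_CORE_LEN - 1,
            a_start, a_start + 1, a_start + 5, a_start + 14)
    extra = tuple(i for i, aa in enumerate(seq)
                  if aa == "C" and i >= spans["signal"][1] and i not in core)

    dibasic: list[int] = []
    furin: list[int] = []
    protected: set[int] = set(core) | set(extra)
    protected |= {12, 13, 14}                     # signal c-region (-3..-1)
    idx = 0
    for tag, segment in pieces:
        if tag == "kr":
            p1 = idx + len(segment) - 1
            dibasic.append(p1)
            protected |= set(range(p1 - 3, p1 + 2))
        elif tag == "furin":
            p1 = idx + len(segment) - 1
            furin.append(p1)
            protected |= set(range(p1 - 3, p1 + 2))
        idx += len(segment)

    domains = _truth_domains(name, spans, len(seq))
    return FamilyTemplate(
        name=name, sequence=seq, signal_end=spans["signal"][1],
        core_cys=core, extra_cys=extra,
        dibasic_sites=tuple(dibasic), furin_sites=tuple(furin),
        domains=domains, intron_plan=tuple(intron_plan),
        protected=frozenset(p for p in protected if 0 <= p < len(seq)),
    )


def _truth_domains(name: str, spans: dict[str, tuple[int, int]],
                   length: int) -> dict[str, tuple[int, int]]:
    """Ground-truth domain intervals implied by the segment plan.

    For two-chain templates the C interval opens right after the first KR
    site (which the B domain keeps); for the single-chain IGF template the
    segment boundary coincides with CB2+1, so the same rule applies.
    """
    signal_end = spans["signal"][1]
    out: dict[str, tuple[int, int]] = {"signal": (0, signal_end)}
    if "F" in spans:
        out["F"] = spans["F"]
    b_start = spans["F"][1] if "F" in spans else signal_end
    a_start, a_end = spans["A"]
    c_start = spans["C"][0]
    out["B"] = (b_start, c_start)
    out["C"] = (c_start, a_start)
    out["A"] = (a_start, a_end)
    if "D" in spans:
        # D runs to the E boundary (the furin site is the last D residue)
        out["D"] = (a_end, spans["E"][0] if "E" in spans else spans["D"][1])
    if "E" in spans:
        out["E"] = spans["E"]
    if a_end < length and "D" not in spans and "E" not in spans:
        out["D"] = (a_end, length)
    return out


@lru_cache(maxsize=None)
def template(family: str) -> FamilyTemplate:
    """The noise-free template for one family (cached; pure)."""
    if family == "GSS":
        return _assemble("GSS", [
            ("signal", SIGNAL),
            ("B", "NQHL"), ("B", _b_core(family)), ("B", "GE"), ("kr", _DIBASIC),
            ("C", "SAGELDDLQVG"), ("kr", _DIBASIC), ("C2", _SPACER),
            ("A", _a_core(family)),
        ], [(44, 1)])
    if family == "octinsulin":
        return _assemble("octinsulin", [
            ("signal", SIGNAL),
            ("B", "NQ"), ("B", "CTEAGSLA"), ("B", _b_core(family)), ("B", "GE"),
            ("kr", _DIBASIC),
            ("C", "SAGELDDLQVG"), ("kr", _DIBASIC), ("C2", _SPACER),
            ("A", _a_core(family)), ("D", "GCDA"),
        ], [(50, 1)])
    if family == "multinsulin":
        return _assemble("multinsulin", [
            ("signal", SIGNAL),
            ("B", "NQHL"), ("B", _b_core(family)), ("B", "GE"), ("kr", _DIBASIC),
            ("C", "SACELDDACQG"), ("kr", _DIBASIC), ("C2", _SPACER),
            ("A", _a_core(family)),
        ], [(18, 2), (26, 1), (44, 1)])
    if family == "dilp7":
        return _assemble("dilp7", [
            ("signal", SIGNAL),
            ("F", "DNTFNGLDALSHETMAQSGNLEAGS"),
            ("B", "NAGELSQA"), ("B", _b_core(family)), ("B", "GE"), ("kr", _DIBASIC),
            ("C", "SAGELDDLQVG"), ("kr", _DIBASIC), ("C2", _SPACER),
            ("A", _a_core(family)),
        ], [(39, 2), (72, 1)])
    if family == "IGF":
        return _assemble("IGF", [
            ("signal", SIGNAL),
            ("B", "NETL"), ("B", _b_core(family)),
            ("C", "GYGSSSAQTN"),
            ("A", _a_core(family)),
            ("D", "KDSERDSE" * 3), ("furin", "KSAR"),
            ("E", "SAEDKDSEAAGA"),
        ], [(37, 1), (80, 0)])
    raise ValueError(f"unknown family: {family!r}")


def _rng(seed: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + streams))


def make_precursor(family: str, seed: int, noise_rate: float = 0.0,
                   ablate: str | None = None) -> SequenceRecord:
    """Instantiate a family template, optionally mutated at ``noise_rate``.

    Every mutation-eligible position is substituted with probability
    ``noise_rate`` by a residue drawn uniformly from the 19 alternatives.
    ``ablate`` removes one defining mark for negative tests:
    ``"core-cys"`` (destroys the framework) or ``"extra-cys"``.
    """
    if not 0.0 <= noise_rate <= 0.2:
        raise ValueError("noise_rate must be in [0, 0.2]")
    tpl = template(family)
    seq = list(tpl.sequence)
    if ablate == "core-cys":
        seq[tpl.core_cys[2]] = "S"
    elif ablate == "extra-cys":
        for idx in tpl.extra_cys:
            seq[idx] = "S"
    elif ablate is not None:
        raise ValueError(f"unknown ablation: {ablate!r}")
    if noise_rate > 0:
        rng = _rng(seed, _FAMILY_CODE[family], 101)
        for i in range(len(seq)):
            if i in tpl.protected:
                continue
            if rng.random() < noise_rate:
                alternatives = AMINO_ACIDS.replace(seq[i], "")
                seq[i] = alternatives[rng.integers(len(alternatives))]
    return SequenceRecord(
        id=f"{family}_{seed}",
        residues="".join(seq),
        description=f"synthetic {family} precursor (seed={seed}, "
                    f"noise={noise_rate:g}, v{GENERATOR_VERSION})",
    )


# ---------------------------------------------------------------------------
# Gene models

_CODONS: dict[str, tuple[str, ...]] = {}


def _codon_table() -> dict[str, tuple[str, ...]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table
        table: dict[str, list[str]] = {}
        for codon, aa in standard_dna_table.forward_table.items():
            table.setdefault(aa, []).append(codon)
        _CODONS.update({aa: tuple(sorted(c)) for aa, c in table.items()})
    return _CODONS


@dataclass(frozen=True)
class SyntheticGene:
    model: GeneModel
    protein: SequenceRecord
    cds: str
    genome: str
    seq_region: str


def make_gene_model(family: str, seed: int) -> SyntheticGene:
    """Emit a gene model whose CDS translates exactly to the family precursor.

    The CDS (protein + stop) is split at the template's planted intron
    positions; intron phases follow the family plan.
    """
    tpl = template(family)
    protein = make_precursor(family, seed, 0.0)
    rng = _rng(seed, _FAMILY_CODE[family], 202)
    codons = _codon_table()
    cds = "".join(
        codons[aa][rng.integers(len(codons[aa]))] for aa in protein.residues
    ) + "TAA"
    cut_offsets = [3 * aa_pos + phase for aa_pos, phase in tpl.intron_plan]
    assert cut_offsets == sorted(cut_offsets) and all(
        0 < off < len(cds) for off in cut_offsets)

    bounds = [0] + cut_offsets + [len(cds)]
    exon_seqs = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    flank = 200
    pos = flank
    exons: list[tuple[int, int]] = []
    genome_parts: list[str] = ["".join(rng.choice(list("ACGT"), flank))]
    for i, exon_seq in enumerate(exon_seqs):
        exons.append((pos, pos + len(exon_seq)))
        genome_parts.append(exon_seq)
        pos += len(exon_seq)
        if i < len(exon_seqs) - 1:
            intron_len = int(rng.integers(120, 321))
            intron = "GT" + "".join(rng.choice(list("ACGT"), intron_len - 4)) + "AG"
            genome_parts.append(intron)
            pos += intron_len
    genome_parts.append("".join(rng.choice(list("ACGT"), flank)))
    region = f"chr_{family}_{seed}"
    model = GeneModel(
        gene_id=f"{family}_{seed}.t1", seq_region=region, strand="+",
        cds_exons=tuple(exons),
    )
    genome = "".join(genome_parts)
    assert str(Seq(cds).translate()) == protein.residues + "*"
    return SyntheticGene(model=model, protein=protein, cds=cds,
                         genome=genome, seq_region=region)


# ---------------------------------------------------------------------------
# Synteny layouts

def make_synteny_layout(kind: str, seed: int) -> list[GeneLocus]:
    """Echinozoa-style clustered layout or Asterozoa-style scattered layout.

    Clustered: octinsulin, IGF, IGF, dilp7 next to one another (IGF between
    octinsulin and dilp7; gaps 20-50 kb) with GSS 6,000,000 bp downstream.
    Scattered: the same five family labels, each on its own sequence region.
    """
    rng = _rng(seed, 303)
    names = [("oct1", "octinsulin"), ("igf1", "IGF"), ("igf2", "IGF"),
             ("dilp7_1", "dilp7"), ("gss1", "GSS")]
    if kind == "echinozoa_clustered":
        loci = []
        pos = int(rng.integers(10_000, 50_000))
        for i, (gene_id, label) in enumerate(names[:4]):
            length = int(rng.integers(2_000, 8_000))
            loci.append(GeneLocus(gene_id, label, "chr1", pos, pos + length,
                                  "+" if rng.random() < 0.5 else "-"))
            pos += length + int(rng.integers(20_000, 50_001))
        gss_start = loci[-1].end + 6_000_000
        loci.append(GeneLocus("gss1", "GSS", "chr1", gss_start,
                              gss_start + int(rng.integers(2_000, 8_000)), "+"))
        return loci
    if kind == "asterozoa_scattered":
        loci = []
        for i, (gene_id, label) in enumerate(names):
            start = int(rng.integers(10_000, 1_000_000))
            length = int(rng.integers(2_000, 8_000))
            loci.append(GeneLocus(gene_id, label, f"scaffold{i + 1}",
                                  start, start + length,
                                  "+" if rng.random() < 0.5 else "-"))
        return loci
    raise ValueError(f"unknown layout kind: {kind!r}")


# ---------------------------------------------------------------------------
# Receptor presets

_LDLA_UNIT = "CQPDCGANDECISNGHQCLPNSCGFNDTSEWC" + "GVDDESDE"
_LRR_UNIT = "LSGLDLSNNQLSGPIPAELGNMTE"
_TM_UNIT = "LAVILGVVFGIALLVISAILL"
_LOOP = "SGDNQTERNSTGQPD"
_LEADER = "M" + "QTNSDAGNQTESHDAGQSN"
_LINKER = "GSTNQDSA"
_TAIL = "NSDEGQTRSNA"


def make_receptor(preset: str, seed: int) -> SequenceRecord:
    """GRL101 preset (12 LDLa + 6 LRR + 7 TM) or single-LDLa LGR (1 + 5 + 7)."""
    if preset == "GRL101":
        n_ldla, n_lrr = 12, 6
    elif preset == "single_LDLa_LGR":
        n_ldla, n_lrr = 1, 5
    else:
        raise ValueError(f"unknown receptor preset: {preset!r}")
    tm_region = (_TM_UNIT + _LOOP) * 6 + _TM_UNIT
    seq = (_LEADER + _LDLA_UNIT * n_ldla + _LINKER + _LRR_UNIT * n_lrr
           + _LINKER + tm_region + _TAIL)
    return SequenceRecord(
        id=f"{preset}_{seed}",
        residues=seq,
        description=f"synthetic {preset} receptor preset (v{GENERATOR_VERSION})",
    )


# ---------------------------------------------------------------------------
# Canonical fixture batteries

def fixture_batch(seed: int, n_per_family: int = 10,
                  noise_rate: float = 0.0) -> list[SequenceRecord]:
    """One batch of precursors across all five families, distinct sub-seeds."""
    records = []
    for family in FAMILIES:
        for k in range(n_per_family):
            rec = make_precursor(family, seed * 1_000 + k, noise_rate)
            records.append(SequenceRecord(
                id=f"{family}_{seed}_{k}", residues=rec.residues,
                description=rec.description))
    return records
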