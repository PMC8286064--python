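"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open; serialized GFF3/TSV coordinates
are 1-based inclusive.  Protein FASTA is uppercased on read, ``*`` stop symbols
are stripped (with a warning), ``X`` is retained as the unknown residue.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord as _BioRecord
from Bio.Seq import Seq

from .scales import AMINO_ACIDS

logger = logging.getLogger("irpkit")

__all__ = [
    "SequenceRecord",
    "GeneModel",
    "GeneLocus",
    "FastaError",
    "GffError",
    "LocusTableError",
    "read_fasta",
    "write_fasta",
    "read_gff3_gene_models",
    "write_gff3_gene_models",
    "read_locus_table",
    "write_locus_table",
    "write_newick",
]

_VALID_RESIDUES = set(AMINO_ACIDS) | {"X"}


class FastaError(ValueError):
    pass


class GffError(ValueError):
    pass


class LocusTableError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with identity and optional known signal cleavage."""

    id: str
    residues: str
    description: str = ""
    signal_cleavage: int | None = None  # known end of the signal peptide, if any

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaError(f"{self.id}: empty sequence")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise FastaError(f"{self.id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    """CDS exon structure of one transcript, genomic 0-based half-open.

    ``cds_exons`` are ordered 5'->3' in transcript orientation (for ``-`` strand
    transcripts the 3'-most genomic exon comes first).
    """

    gene_id: str
    seq_region: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise GffError(f"{self.gene_id}: strand must be + or -")
        for start, end in self.cds_exons:
            if start >= end or start < 0:
                raise GffError(f"{self.gene_id}: bad exon interval ({start},{end})")
        genomic = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise GffError(f"{self.gene_id}: overlapping CDS exons")

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(end - start for start, end in self.cds_exons)

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def complete(self) -> bool:
        return self.cds_length % 3 == 0


@dataclass(frozen=True)
class GeneLocus:
    """One gene's span on a sequence region, for synteny analysis."""

    gene_id: str
    family_label: str
    seq_region: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise LocusTableError(
                f"{self.gene_id}: require 0 <= start < end, got {self.start}..{self.end}"
            )


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased; ``*`` stops are stripped with a warning; duplicate
    ids raise an error naming the id.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate sequence id: {rec.id}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace(" ", "")
        if "*" in residues:
            warnings.warn(f"{rec.id}: stripped '*' stop symbol(s)")
            residues = residues.replace("*", "")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# --------------------------------------------------------------------------
# GFF3 gene models

def read_gff3_gene_models(path: str | Path) -> list[GeneModel]:
    """Read CDS features grouped by their ``Parent`` attribute.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    groups: dict[str, list] = {}
    order: list[str] = []
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent")
        if not parents:
            raise GffError(f"CDS at {feat.seqid}:{feat.start}-{feat.end} has no Parent")
        for parent in parents:
            if parent not in groups:
                groups[parent] = []
                order.append(parent)
            groups[parent].append(feat)
    models: list[GeneModel] = []
    for parent in order:
        feats = groups[parent]
        strands = {f.strand for f in feats}
        if len(strands) != 1 or not strands <= {"+", "-"}:
            raise GffError(f"{parent}: mixed or missing strands {sorted(strands)}")
        strand = strands.pop()
        exons = sorted((f.start - 1, f.end) for f in feats)
        if strand == "-":
            exons.reverse()
        models.append(GeneModel(
            gene_id=parent,
            seq_region=feats[0].seqid,
            strand=strand,
            cds_exons=tuple(exons),
        ))
    if not models:
        raise GffError(f"{path}: no CDS features found")
    return models


def write_gff3_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Serialize gene models as gene/mRNA/CDS GFF3 lines (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for model in models:
        genomic = sorted(model.cds_exons)
        gstart, gend = genomic[0][0] + 1, genomic[-1][1]
        lines.append("\t".join([
            model.seq_region, "irpkit", "gene", str(gstart), str(gend), ".",
            model.strand, ".", f"ID=gene:{model.gene_id}",
        ]))
        lines.append("\t".join([
            model.seq_region, "irpkit", "mRNA", str(gstart), str(gend), ".",
            model.strand, ".", f"ID={model.gene_id};Parent=gene:{model.gene_id}",
        ]))
        for start, end in genomic:
            lines.append("\t".join([
                model.seq_region, "irpkit", "CDS", str(start + 1), str(end), ".",
                model.strand, "0", f"Parent={model.gene_id}",
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Locus tables (synteny input)

_LOCUS_COLUMNS = ["gene_id", "family_label", "seq_region", "start", "end", "strand"]


def read_locus_table(path: str | Path) -> list[GeneLocus]:
    """Read a TSV locus table; 1-based inclusive coordinates on disk."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "seq_region": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise LocusTableError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in _LOCUS_COLUMNS if c not in df.columns]
    if missing:
        raise LocusTableError(f"{path}: missing columns {missing}")
    for col in ("start", "end"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise LocusTableError(f"{path}: non-integer coordinates in column {col}")
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        raise LocusTableError(
            f"{path}: require start < end, violated by "
            f"{', '.join(bad['gene_id'].astype(str))}")
    loci = [
        GeneLocus(
            gene_id=row.gene_id, family_label=row.family_label,
            seq_region=row.seq_region,
            start=int(row.start) - 1, end=int(row.end), strand=row.strand,
        )
        for row in df.itertuples()
    ]
    return sorted(loci, key=lambda l: (l.seq_region, l.start, l.gene_id))


def write_locus_table(loci: Iterable[GeneLocus], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (l.gene_id, l.family_label, l.seq_region, l.start + 1, l.end, l.strand)
            for l in loci
        ],
        columns=_LOCUS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Newick

def write_newick(tree) -> str:
    """Serialize a :class:`irpkit.tree.TreeNode` to a Newick string.

    Branch lengths are written at full (repr) precision; labels containing
    Newick metacharacters are single-quoted; duplicate leaf labels are an error.
    """
    from .tree import TreeNode  # local import: tree does not depend on io

    if not isinstance(tree, TreeNode):
        raise TypeError("write_newick expects an irpkit.tree.TreeNode")
    labels = [leaf.label for leaf in tree.leaves()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")

    def fmt_label(label: str) -> str:
        if label and not any(c in label for c in " \t\n()[]':;,"):
            return label
        return "'" + label.replace("'", "''") + "'"

    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            body = fmt_label(node.label)
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                body += fmt_label(node.label)
        if node.length is not None:
            body += f":{node.length!r}"
        return body

    return fmt(tree) + ";"
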