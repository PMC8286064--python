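"""Precursor domain segmentation: signal / F / B / C / A / D / E.

The A- and B-domains correspond to the insulin A- and B-chains, the C-domain to
the connecting peptide.  IGF-type precursors extend the A-chain with a D domain
and a furin-removed E domain; dilp7-type precursors carry an N-terminal
extension of the B-chain (the F domain).  Segmentation is driven by the
cysteine framework and the accepted cleavage sites; the present intervals are
disjoint, ordered and cover the whole precursor.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cleavage import CleavageSite
from .config import Config
from .cys_framework import CysFramework

__all__ = ["DomainAnnotation", "TailFeatures", "SegmentationError",
           "segment_domains", "tail_features", "f_domain_metrics",
           "domain_gff3_lines"]

DOMAIN_ORDER = ("signal", "F", "B", "C", "A", "D", "E")

_GFF_TYPES = {
    "signal": "signal_peptide", "F": "F_domain", "B": "B_domain",
    "C": "C_domain", "A": "A_domain", "D": "D_domain", "E": "E_domain",
}


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class DomainAnnotation:
    """Ordered 0-based half-open intervals per domain tag."""

    intervals: dict[str, tuple[int, int]]
    chain_mode: str  # single_chain | two_chain

    def domain_at(self, idx: int) -> str | None:
        for tag, (start, end) in self.intervals.items():
            if start <= idx < end:
                return tag
        return None

    def length(self, tag: str) -> int:
        if tag not in self.intervals:
            return 0
        start, end = self.intervals[tag]
        return end - start

    def extract(self, seq: str, tag: str) -> str:
        if tag not in self.intervals:
            return ""
        start, end = self.intervals[tag]
        return seq[start:end]


@dataclass(frozen=True)
class TailFeatures:
    """Charge composition of the C-terminal (D+E) extension."""

    tail_len: int
    basic_fraction: float
    charged_fraction: float
    absent: bool = False


def segment_domains(seq: str, signal_pos: int, framework: CysFramework,
                    sites: list[CleavageSite],
                    config: Config | None = None) -> DomainAnnotation:
    """Partition the precursor into domains from framework + accepted sites.

    B starts at the latest of: the signal end, the boundary after the nearest
    accepted upstream cleavage site, or ``cb1 - b_lead``.  The region between
    the signal end and the B start becomes a distinct F domain when it reaches
    ``f_min`` residues, otherwise it is merged into B.  C runs between the
    accepted sites flanking it (two-chain) or simply between CB2 and CA1
    (single-chain); the mode is ``two_chain`` iff accepted sites flank C on
    both sides.  Downstream of CA4 an accepted furin site splits D from E;
    without one the whole extension is D.
    """
    cfg = config or Config()
    if framework is None:
        raise SegmentationError("cannot segment: no cysteine framework")
    L = len(seq)
    fw = framework
    accepted = [s for s in sites if s.accepted]

    # --- B start and the F domain
    b_lead = cfg["domains.b_lead"]
    upstream = [s.pos + 1 for s in accepted if s.pos < fw.cb1 and s.pos + 1 > signal_pos]
    b_start = max([signal_pos, fw.cb1 - b_lead] + upstream)
    b_start = min(b_start, fw.cb1)
    if b_start < signal_pos:
        raise SegmentationError(
            f"CB1 at {fw.cb1} lies inside the predicted signal peptide (end {signal_pos})")
    if b_start - signal_pos >= cfg["domains.f_min"]:
        f_interval = (signal_pos, b_start)
    else:
        f_interval = None
        b_start = signal_pos

    # --- sites flanking the C region
    # a single interior site cannot flank C on both ends, hence >= 2
    between = [s for s in accepted if fw.cb2 < s.pos < fw.ca1]
    if len(between) >= 2:
        site_after_b = min(between, key=lambda s: s.pos)
        b_end = site_after_b.pos + 1
        chain_mode = "two_chain"
    else:
        b_end = fw.cb2 + 1
        chain_mode = "single_chain"

    intervals: dict[str, tuple[int, int]] = {"signal": (0, signal_pos)}
    if f_interval:
        intervals["F"] = f_interval
    intervals["B"] = (b_start, b_end)
    intervals["C"] = (b_end, fw.ca1)
    a_end = fw.ca4 + 1
    intervals["A"] = (fw.ca1, a_end)

    # --- D / E split at the first accepted furin site after CA4
    furin_after = [s for s in accepted
                   if s.kind.startswith("furin") and s.pos > fw.ca4]
    if furin_after:
        first = min(furin_after, key=lambda s: s.pos)
        intervals["D"] = (a_end, first.pos + 1)
        if first.pos + 1 < L:
            intervals["E"] = (first.pos + 1, L)
    elif a_end < L:
        intervals["D"] = (a_end, L)

    annotation = DomainAnnotation(intervals=intervals, chain_mode=chain_mode)
    _validate_partition(annotation, fw, L)
    return annotation


def _validate_partition(annotation: DomainAnnotation, fw: CysFramework, L: int) -> None:
    present = [(tag, annotation.intervals[tag]) for tag in DOMAIN_ORDER
               if tag in annotation.intervals]
    cursor = 0
    for tag, (start, end) in present:
        if start != cursor or end < start:
            raise SegmentationError(
                f"domain partition broken at {tag}: [{start},{end}) after {cursor}")
        cursor = end
    if cursor != L:
        raise SegmentationError(f"domains cover [0,{cursor}) of length-{L} precursor")
    b = annotation.intervals["B"]
    a = annotation.intervals["A"]
    if not (b[0] <= fw.cb1 < b[1] and b[0] <= fw.cb2 < b[1]):
        raise SegmentationError("B domain does not contain CB1/CB2")
    if not all(a[0] <= c < a[1] for c in (fw.ca1, fw.ca2, fw.ca3, fw.ca4)):
        raise SegmentationError("A domain does not contain CA1..CA4")


def tail_features(seq: str, annotation: DomainAnnotation) -> TailFeatures:
    """Charge composition of the concatenated D and E intervals."""
    tail = annotation.extract(seq, "D") + annotation.extract(seq, "E")
    n = len(tail)
    if n == 0:
        return TailFeatures(0, 0.0, 0.0, absent=True)
    basic = sum(tail.count(aa) for aa in "KR")
    acidic = sum(tail.count(aa) for aa in "DE")
    return TailFeatures(n, basic / n, (basic + acidic) / n)


def f_domain_metrics(seq: str, annotation: DomainAnnotation,
                     references: list[str] | None = None,
                     config: Config | None = None) -> tuple[int, float | None]:
    """Length of the F domain and, given references, mean pairwise identity.

    Identity is computed per reference from a global alignment (the similarity
    tree aligner) as matches over alignment columns, then averaged.
    """
    f_seq = annotation.extract(seq, "F")
    f_len = len(f_seq)
    if not references or f_len == 0:
        return f_len, None
    from .tree import pairwise_align  # deferred: tree pulls in Bio.Align

    identities = []
    for ref in references:
        _score, (row_a, row_b) = pairwise_align(f_seq, ref, config)
        cols = len(row_a)
        matches = sum(a == b and a != "-" for a, b in zip(row_a, row_b))
        identities.append(matches / cols if cols else 0.0)
    return f_len, sum(identities) / len(identities)


def domain_gff3_lines(record_id: str, annotation: DomainAnnotation) -> list[str]:
    """One GFF3-style feature line per domain (1-based inclusive)."""
    lines = []
    for tag in DOMAIN_ORDER:
        if tag not in annotation.intervals:
            continue
        start, end = annotation.intervals[tag]
        lines.append("\t".join([
            record_id, "irpkit", _GFF_TYPES[tag], str(start + 1), str(end), ".",
            "+", ".", f"ID={record_id}:{tag}",
        ]))
    return lines
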