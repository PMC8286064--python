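"""Detection of the canonical insulin six-cysteine framework.

The insulin superfamily core consists of two B-chain cysteines (CB1, CB2) and
four A-chain cysteines (CA1..CA4) with CA1/CA2 adjacent.  The A-chain motif is
C-C-x(2..6)-C-x(6..14)-C; the B-chain cysteines lie 8..16 residues apart,
5..80 residues upstream of CA1 (the C-domain span).  Spacing bounds generalize
the human insulin spacings (3, 8, 12) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import Config

__all__ = ["CysFramework", "find_core_framework", "classify_extra_cysteines",
           "infer_bridges", "BridgeCall"]

#: Canonical three-bridge pairing of the six core cysteines.
CANONICAL_PAIRING = (("CA1", "CA3"), ("CA2", "CB1"), ("CA4", "CB2"))


@dataclass(frozen=True)
class CysFramework:
    """Indexed positions (0-based) of the six core cysteines."""

    cb1: int
    cb2: int
    ca1: int
    ca2: int
    ca3: int
    ca4: int
    extra_cys: tuple[tuple[int, str], ...] = ()
    score: int = 0

    def __post_init__(self) -> None:
        order = (self.cb1, self.cb2, self.ca1, self.ca2, self.ca3, self.ca4)
        if list(order) != sorted(order) or len(set(order)) != 6:
            raise ValueError(f"core cysteines out of order: {order}")
        if self.ca2 != self.ca1 + 1:
            raise ValueError("CA1 and CA2 must be adjacent")

    @property
    def core_positions(self) -> tuple[int, ...]:
        return (self.cb1, self.cb2, self.ca1, self.ca2, self.ca3, self.ca4)

    def with_extras(self, extras) -> "CysFramework":
        return CysFramework(*self.core_positions, extra_cys=tuple(extras),
                            score=self.score)


def find_core_framework(seq: str, config: Config | None = None) -> CysFramework | None:
    """Locate the six-cysteine core, or return None if no assignment fits.

    Scans A-chain motifs from the C-terminus; the highest-scoring consistent
    assignment wins (score = number of spacings at their modal human-insulin
    values 3, 8, 12).  Ties prefer the most C-terminal A-chain motif, then the
    smallest (cb1, cb2).
    """
    cfg = config or Config()
    if len(seq) < 40:
        return None
    cys = [i for i, aa in enumerate(seq) if aa == "C"]
    if len(cys) < 6:
        return None
    cys_set = set(cys)
    a_lo, a_hi = cfg["framework.a_gap_min"], cfg["framework.a_gap_max"]
    b_lo, b_hi = cfg["framework.b_gap_min"], cfg["framework.b_gap_max"]
    p_lo, p_hi = cfg["framework.bpair_min"], cfg["framework.bpair_max"]
    c_lo, c_hi = cfg["framework.c_span_min"], cfg["framework.c_span_max"]

    best: tuple | None = None
    best_fw: CysFramework | None = None
    for ca1 in reversed(cys):
        ca2 = ca1 + 1
        if ca2 not in cys_set:
            continue
        for ca3 in cys:
            gap_a = ca3 - ca2 - 1
            if not (a_lo <= gap_a <= a_hi):
                continue
            for ca4 in cys:
                gap_b = ca4 - ca3 - 1
                if not (b_lo <= gap_b <= b_hi):
                    continue
                for cb2 in cys:
                    span = ca1 - cb2
                    if not (c_lo <= span <= c_hi):
                        continue
                    for cb1 in cys:
                        pair = cb2 - cb1
                        if not (p_lo <= pair <= p_hi):
                            continue
                        score = (
                            (gap_a == cfg["framework.a_gap_mode"])
                            + (gap_b == cfg["framework.b_gap_mode"])
                            + (pair == cfg["framework.bpair_mode"])
                        )
                        # maximize score, then most C-terminal A motif,
                        # then smallest (cb1, cb2)
                        key = (score, ca1, ca3, ca4, -cb1, -cb2)
                        if best is None or key > best:
                            best = key
                            best_fw = CysFramework(
                                cb1=cb1, cb2=cb2, ca1=ca1, ca2=ca2,
                                ca3=ca3, ca4=ca4, score=score,
                            )
    return best_fw


def classify_extra_cysteines(seq: str, framework: CysFramework, domains) -> list[tuple[int, str]]:
    """Report every mature-region cysteine outside the core with its domain.

    ``domains`` is a :class:`irpkit.domains.DomainAnnotation`; calling this
    before segmentation is an error.
    """
    if framework is None:
        raise ValueError("framework required before extra-cysteine classification")
    if domains is None:
        raise ValueError("domain segmentation required before extra-cysteine classification")
    core = set(framework.core_positions)
    mature_start = domains.intervals.get("signal", (0, 0))[1]
    extras: list[tuple[int, str]] = []
    for idx, aa in enumerate(seq):
        if aa != "C" or idx in core or idx < mature_start:
            continue
        extras.append((idx, domains.domain_at(idx) or "?"))
    return extras


@dataclass(frozen=True)
class BridgeCall:
    n_bridges: int
    pairing: tuple[tuple[str, str], ...]
    unpaired_warning: bool = False


def infer_bridges(framework: CysFramework) -> BridgeCall:
    """Infer the disulfide-bridge count from the framework.

    Six core cysteines give the canonical three bridges; each complete extra
    pair adds one bridge (the pair is assumed to bond together).  An odd extra
    count reports the paired subset with a warning flag.
    """
    if framework is None:
        raise ValueError("framework required")
    n_extra = len(framework.extra_cys)
    pairing = list(CANONICAL_PAIRING)
    extra_sorted = sorted(idx for idx, _tag in framework.extra_cys)
    for k in range(n_extra // 2):
        pairing.append((f"X{2 * k + 1}", f"X{2 * k + 2}"))
    return BridgeCall(
        n_bridges=3 + n_extra // 2,
        pairing=tuple(pairing),
        unpaired_warning=bool(n_extra % 2),
    )
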