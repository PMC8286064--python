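"""Cleavage-site prediction: signal peptide, furin and neuroendocrine convertases.

Furin recognizes K/R-X-K/R-R (the strong consensus); the human IGF precursors
are processed at KSAR and KSER, which only satisfy a relaxed K/R-X-X-R form, so
the rule is two-tiered (``furin_strong`` / ``furin_weak``).  PC1/3-PC2 sites use
the KR consensus, subject to steric-hindrance exclusions: a bulky or proline
residue at P1', a proline just before the site, or a core disulfide cysteine
nearby all block cleavage.  Sites are reported with a full reason trail rather
than a probability - these are predictions, not certainties.

The signal-peptide heuristic is a documented stand-in for a full predictor: it
combines the (-3,-1) small-residue rule with mean Kyte-Doolittle hydropathy of
the h-region.  A user-supplied cleavage position always wins.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import Config
from .cys_framework import CysFramework
from .scales import window_mean

__all__ = ["CleavageSite", "SignalError", "predict_signal_cleavage",
           "find_furin_sites", "find_dibasic_sites", "find_sites"]


class SignalError(ValueError):
    pass


@dataclass(frozen=True)
class CleavageSite:
    """A candidate cleavage after residue ``pos`` (the P1 residue)."""

    pos: int
    kind: str           # furin_strong | furin_weak | dibasic | monobasic | signal
    motif: str          # residue window P6..P2'
    verdict: str        # accepted | rejected
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.verdict == "rejected" and not self.reasons:
            raise ValueError("rejected sites must carry at least one reason")

    @property
    def accepted(self) -> bool:
        return self.verdict == "accepted"


def _window(seq: str, pos: int) -> str:
    """P6..P2' context window around the P1 residue at ``pos``."""
    lo, hi = max(0, pos - 5), min(len(seq), pos + 3)
    return seq[lo:hi]


def predict_signal_cleavage(seq: str, override: int | None = None,
                            config: Config | None = None) -> int:
    """Predict the end of the signal peptide (index of the first mature residue).

    Candidate positions p in [signal_min, signal_max] score +1 for a small
    residue (A/G/S/C/T) at p-1 and at p-3, plus the mean Kyte-Doolittle
    hydropathy of the h-region window p-13..p-6 when it reaches the configured
    minimum.  Ties go to the smallest p.
    """
    if override is not None:
        return override
    cfg = config or Config()
    if len(seq) < 25:
        raise SignalError("sequence too short for signal-peptide prediction")
    small = set(cfg["cleavage.small_residues"])
    hydro_min = cfg["cleavage.signal_hydro_min"]
    best_p, best_score = None, 0.0
    lo = cfg["cleavage.signal_min"]
    hi = min(cfg["cleavage.signal_max"], len(seq) - 5)
    for p in range(lo, hi + 1):
        score = 0.0
        if seq[p - 1] in small:
            score += 1.0
        if seq[p - 3] in small:
            score += 1.0
        hydro = window_mean(seq, p - 13, p - 6)
        if hydro >= hydro_min:
            score += hydro
        if score > best_score:
            best_p, best_score = p, score
    if best_p is None:
        raise SignalError("no signal peptide detected")
    return best_p


def find_furin_sites(seq: str, start: int, config: Config | None = None) -> list[CleavageSite]:
    """Scan for furin sites downstream of ``start`` (end of the signal peptide).

    P4..P1 = [KR]-X-[KR]-R is the strong consensus; [KR]-X-X-R the weak tier
    (covering the human IGF examples KSAR/KSER).  Proline at P1' rejects.
    """
    sites: list[CleavageSite] = []
    for pos in range(max(start + 3, 3), len(seq)):
        if seq[pos] != "R":
            continue
        p4, p3, p2 = seq[pos - 3], seq[pos - 2], seq[pos - 1]
        if p4 not in "KR":
            continue
        kind = "furin_strong" if p2 in "KR" else "furin_weak"
        reasons: list[str] = []
        if pos + 1 < len(seq) and seq[pos + 1] == "P":
            reasons.append("P1'-proline")
        sites.append(CleavageSite(
            pos=pos, kind=kind, motif=_window(seq, pos),
            verdict="rejected" if reasons else "accepted",
            reasons=tuple(reasons),
        ))
    return sites


_DIBASIC_MOTIFS = {
    "KR": "cleavage.enable_kr",
    "RR": "cleavage.enable_rr",
    "KK": "cleavage.enable_kk",
    "RK": "cleavage.enable_rk",
}


def find_dibasic_sites(seq: str, start: int, framework: CysFramework | None = None,
                       config: Config | None = None) -> list[CleavageSite]:
    """Scan for PC1/3-PC2 convertase sites with steric-hindrance exclusions.

    Candidate motifs (P2-P1) are KR by default; RR/KK/RK and monobasic R can be
    enabled in config.  Exclusions: bulky P1' residue, P1' proline, proline at
    P3/P4, or any core-framework cysteine within the disulfide window of P1.
    """
    cfg = config or Config()
    bulky = set(cfg["cleavage.bulky_p1prime"])
    w = cfg["cleavage.disulfide_window"]
    core = set(framework.core_positions) if framework is not None else set()
    enabled = [m for m, key in _DIBASIC_MOTIFS.items() if cfg[key]]
    monobasic = cfg["cleavage.enable_monobasic"]

    sites: list[CleavageSite] = []
    for pos in range(max(start + 1, 1), len(seq)):
        motif2 = seq[pos - 1:pos + 1]
        if motif2 in enabled:
            kind = "dibasic"
        elif monobasic and seq[pos] == "R" and motif2 not in _DIBASIC_MOTIFS:
            kind = "monobasic"
        else:
            continue
        reasons: list[str] = []
        p1prime = seq[pos + 1] if pos + 1 < len(seq) else ""
        if p1prime in bulky:
            reasons.append("bulky-P1'")
        if p1prime == "P":
            reasons.append("P1'-proline")
        if (pos >= 2 and seq[pos - 2] == "P") or (pos >= 3 and seq[pos - 3] == "P"):
            reasons.append("pre-site-proline")
        if any(abs(pos - c) <= w for c in core):
            reasons.append("disulfide-proximity")
        sites.append(CleavageSite(
            pos=pos, kind=kind, motif=_window(seq, pos),
            verdict="rejected" if reasons else "accepted",
            reasons=tuple(reasons),
        ))
    return sites


def find_sites(seq: str, start: int, framework: CysFramework | None = None,
               config: Config | None = None) -> list[CleavageSite]:
    """All furin + convertase sites downstream of the signal, sorted by position."""
    sites = find_furin_sites(seq, start, config) + find_dibasic_sites(
        seq, start, framework, config)
    return sorted(sites, key=lambda s: (s.pos, s.kind))
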