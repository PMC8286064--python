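"""Receptor ectodomain annotation: 7-TM detection, LRR and LDLa repeat counting.

Candidate irp receptors of the LGR class carry leucine-rich repeats (LRRs) and,
in some subtypes, LDL-receptor class A (LDLa) repeats ahead of the seven
transmembrane helices.  GRL101-type receptors combine a long LDLa series with
LRRs; the gonadulin/dilp7-receptor type carries a single (occasionally
duplicated) LDLa.  TM segments are found by Kyte-Doolittle hydropathy scanning;
the repeats by regex-style consensus patterns standing in for profile models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .config import Config
from .scales import hydropathy_profile

__all__ = ["ReceptorAnnotation", "hydropathy_tm_segments", "find_ldla_repeats",
           "find_lrr_repeats", "receptor_summary", "annotate_receptor"]


@dataclass(frozen=True)
class ReceptorAnnotation:
    tm_segments: tuple[tuple[int, int], ...]
    lrr_repeats: tuple[tuple[int, int], ...]
    ldla_repeats: tuple[tuple[int, int], ...]
    architecture_call: str = "other"

    @property
    def n_tm(self) -> int:
        return len(self.tm_segments)


def hydropathy_tm_segments(seq: str, config: Config | None = None
                           ) -> list[tuple[int, int]]:
    """Maximal runs of high mean Kyte-Doolittle hydropathy (centered window).

    Runs shorter than the minimum are discarded; runs separated by fewer than
    the merge gap are merged first.
    """
    cfg = config or Config()
    window = cfg["receptor.kd_window"]
    if len(seq) < window:
        return []
    threshold = cfg["receptor.kd_threshold"]
    profile = hydropathy_profile(seq)
    kernel = np.ones(window) / window
    means = np.convolve(profile, kernel, mode="valid")  # means[i] = window at i..i+w
    half = window // 2
    marked = np.zeros(len(seq), dtype=bool)
    marked[half:half + len(means)] = means > threshold

    runs: list[list[int]] = []
    for i, flag in enumerate(marked):
        if flag:
            if runs and i == runs[-1][1]:
                runs[-1][1] = i + 1
            else:
                runs.append([i, i + 1])
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < cfg["receptor.tm_merge_gap"]:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    min_run = cfg["receptor.tm_min_run"]
    return [(s, e) for s, e in merged if e - s >= min_run]


#: Six-cysteine LDLa module (non-greedy: shortest match per anchor).
_LDLA_RE = re.compile(
    r"C.{2,7}?C.{3,9}?C.{4,10}?C.{2,8}?C.{5,14}?C")

#: LRR consensus J-x-x-J-x-J-x-x-[NC]-x-J with J in {L,I,V,F}.
_LRR_RE = re.compile(
    r"[LIVF]..[LIVF].[LIVF]..[NC].[LIVF]")


def _has_acidic_cluster(seq: str, start: int, config: Config) -> bool:
    follow = config["receptor.ldla_follow"]
    wlen = config["receptor.ldla_acid_window"]
    need = config["receptor.ldla_acid_min"]
    for i in range(start, min(start + follow, len(seq))):
        window = seq[i:i + wlen]
        if sum(window.count(aa) for aa in "DE") >= need:
            return True
    return False


def find_ldla_repeats(seq: str, config: Config | None = None
                      ) -> list[tuple[int, int]]:
    """Non-overlapping LDLa matches followed by an acidic (D/E) cluster.

    Greedy left-to-right with the shortest match per anchor; a match without
    at least ``ldla_acid_min`` acidic residues in an ``ldla_acid_window``-long
    window starting within ``ldla_follow`` residues is not counted.
    """
    cfg = config or Config()
    repeats: list[tuple[int, int]] = []
    pos = 0
    while True:
        match = _LDLA_RE.search(seq, pos)
        if match is None:
            return repeats
        if _has_acidic_cluster(seq, match.end(), cfg):
            repeats.append((match.start(), match.end()))
            pos = match.end()
        else:
            pos = match.start() + 1


def find_lrr_repeats(seq: str, config: Config | None = None
                     ) -> list[tuple[int, int]]:
    """LRR consensus matches; matches closer than the collapse distance to the
    previously kept one are collapsed into it."""
    cfg = config or Config()
    collapse = cfg["receptor.lrr_collapse"]
    kept: list[tuple[int, int]] = []
    for match in _LRR_RE.finditer(seq):
        if kept and match.start() - kept[-1][0] < collapse:
            continue
        kept.append((match.start(), match.end()))
    return kept


def receptor_summary(annotation: ReceptorAnnotation) -> str:
    """Architecture call from TM/LDLa/LRR counts."""
    n_tm = annotation.n_tm
    n_ldla = len(annotation.ldla_repeats)
    n_lrr = len(annotation.lrr_repeats)
    if n_tm == 7 and n_ldla >= 6 and n_lrr >= 3:
        return "GRL101_like"
    if n_tm == 7 and n_ldla in (1, 2) and n_lrr >= 3:
        return "single_LDLa_LGR_like"
    return "other"


def annotate_receptor(seq: str, config: Config | None = None) -> ReceptorAnnotation:
    """Run the full receptor annotation on one protein sequence."""
    cfg = config or Config()
    partial = ReceptorAnnotation(
        tm_segments=tuple(hydropathy_tm_segments(seq, cfg)),
        lrr_repeats=tuple(find_lrr_repeats(seq, cfg)),
        ldla_repeats=tuple(find_ldla_repeats(seq, cfg)),
    )
    return ReceptorAnnotation(
        tm_segments=partial.tm_segments,
        lrr_repeats=partial.lrr_repeats,
        ldla_repeats=partial.ldla_repeats,
        architecture_call=receptor_summary(partial),
    )
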