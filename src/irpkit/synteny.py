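"""Microsynteny: cluster irp loci, measure inter-gene gaps, compare species.

Gaps are measured end-to-start between coding regions, in kb, matching how
inter-gene distances are usually reported for these clusters; the default
1 Mb joining threshold separates "next to one another" distances (tens of kb)
from the multi-megabase distances at which a GSS gene sits from the rest.
Strand is recorded but does not affect clustering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .config import Config
from .io import GeneLocus

__all__ = ["SyntenyCluster", "cluster_loci", "conserved_arrangement_check",
           "compare_layouts", "clusters_to_table"]


@dataclass(frozen=True)
class SyntenyCluster:
    seq_region: str
    members: tuple[GeneLocus, ...]
    gaps_kb: tuple[float, ...]

    def __post_init__(self) -> None:
        starts = [m.start for m in self.members]
        if starts != sorted(starts):
            raise ValueError("cluster members must be sorted by start")
        if len(self.gaps_kb) != len(self.members) - 1:
            raise ValueError("need exactly one gap per adjacent member pair")

    @property
    def family_composition(self) -> tuple[str, ...]:
        return tuple(sorted(m.family_label for m in self.members))


def _gap_bp(left: GeneLocus, right: GeneLocus) -> int:
    return max(0, right.start - left.end)  # overlapping loci get gap 0


def cluster_loci(loci: Iterable[GeneLocus], max_gap: int | None = None,
                 config: Config | None = None) -> list[SyntenyCluster]:
    """Maximal runs of same-region loci whose successive gaps are <= max_gap."""
    cfg = config or Config()
    if max_gap is None:
        max_gap = cfg["synteny.max_gap"]
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    by_region: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_region.setdefault(locus.seq_region, []).append(locus)
    clusters: list[SyntenyCluster] = []
    for region in sorted(by_region):
        members = sorted(by_region[region], key=lambda l: (l.start, l.gene_id))
        run: list[GeneLocus] = [members[0]]
        for locus in members[1:]:
            if _gap_bp(run[-1], locus) <= max_gap:
                run.append(locus)
            else:
                clusters.append(_make_cluster(region, run))
                run = [locus]
        clusters.append(_make_cluster(region, run))
    return clusters


def _make_cluster(region: str, run: list[GeneLocus]) -> SyntenyCluster:
    gaps = tuple(_gap_bp(a, b) / 1000.0 for a, b in zip(run, run[1:]))
    return SyntenyCluster(seq_region=region, members=tuple(run), gaps_kb=gaps)


_OCT_LABELS = {"octinsulin", "gonadulin"}


def conserved_arrangement_check(cluster: SyntenyCluster) -> str:
    """Test the conserved octinsulin-IGF-dilp7 triplet with IGF in the middle."""
    labels = [m.family_label for m in cluster.members]
    oct_pos = [i for i, l in enumerate(labels) if l in _OCT_LABELS]
    igf_pos = [i for i, l in enumerate(labels) if l == "IGF"]
    d7_pos = [i for i, l in enumerate(labels) if l == "dilp7"]
    for g in igf_pos:
        if any(o < g for o in oct_pos) and any(d > g for d in d7_pos):
            return "triplet_with_IGF_middle"
        if any(d < g for d in d7_pos) and any(o > g for o in oct_pos):
            return "triplet_with_IGF_middle"
    return "other"


def compare_layouts(layouts: Mapping[str, list[SyntenyCluster]]) -> pd.DataFrame:
    """Shared cluster family-compositions per species pair.

    Returns one row per (species pair, composition) with a same/different
    verdict: 'shared' when both species have a cluster of that composition.
    """
    if len(layouts) < 2:
        raise ValueError("need >=2 species to compare layouts")
    rows = []
    species = sorted(layouts)
    comps = {sp: Counter(c.family_composition for c in layouts[sp])
             for sp in species}
    for i, sp_a in enumerate(species):
        for sp_b in species[i + 1:]:
            all_comps = sorted(set(comps[sp_a]) | set(comps[sp_b]))
            for comp in all_comps:
                n_a, n_b = comps[sp_a][comp], comps[sp_b][comp]
                rows.append({
                    "species_a": sp_a, "species_b": sp_b,
                    "composition": "+".join(comp),
                    "n_a": n_a, "n_b": n_b,
                    "verdict": "shared" if n_a and n_b else "different",
                })
    return pd.DataFrame(rows, columns=["species_a", "species_b", "composition",
                                       "n_a", "n_b", "verdict"])


def clusters_to_table(clusters: list[SyntenyCluster]) -> pd.DataFrame:
    rows = []
    for idx, cluster in enumerate(clusters):
        rows.append({
            "cluster_id": f"cluster{idx + 1}",
            "seq_region": cluster.seq_region,
            "members": ",".join(f"{m.gene_id}({m.family_label}{m.strand})"
                                for m in cluster.members),
            "gaps_kb": ",".join(f"{g:g}" for g in cluster.gaps_kb),
            "arrangement_flag": conserved_arrangement_check(cluster),
        })
    return pd.DataFrame(rows, columns=["cluster_id", "seq_region", "members",
                                       "gaps_kb", "arrangement_flag"])
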