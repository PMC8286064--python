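"""Sequence similarity trees: global alignment distances + neighbor joining.

These trees illustrate similarity between precursors, not phylogeny - the
superfamily is too variable for the usual phylogenetic assumptions to hold.
A simple deterministic pipeline (BLOSUM62 global alignment with affine gaps,
p or Poisson distance, canonical neighbor joining) keeps every step testable.
By default only the concatenated B+A core domains are compared, since the
D/E extensions are conserved only between closely related species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .config import Config
from .scales import AMINO_ACIDS

logger = logging.getLogger("irpkit")

__all__ = ["DistanceMatrix", "TreeNode", "pairwise_align", "distance",
           "neighbor_joining", "family_tree", "leaf_distances", "splits"]


@dataclass
class TreeNode:
    """Node of a (generally unrooted) tree; the root of an NJ tree is the
    trifurcation created at the final join."""

    label: str = ""
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.d, dtype=float)
        if arr.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrix must be symmetric")
        if (arr < 0).any() or not np.allclose(np.diag(arr), 0.0):
            raise ValueError("distances must be >= 0 with a zero diagonal")
        object.__setattr__(self, "d", arr)


_VALID = set(AMINO_ACIDS) | {"X"}


def _aligner(config: Config | None) -> Align.PairwiseAligner:
    cfg = config or Config()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # "gap open 11, extend 1": a length-L gap costs 11 + L
    aligner.open_gap_score = -(cfg["tree.gap_open"] + cfg["tree.gap_extend"])
    aligner.extend_gap_score = -float(cfg["tree.gap_extend"])
    return aligner


def pairwise_align(a: str, b: str, config: Config | None = None
                   ) -> tuple[float, tuple[str, str]]:
    """Optimal global alignment under BLOSUM62 with affine gaps.

    Returns the score and the pair of gapped rows; the traceback is
    deterministic (first optimal alignment in the aligner's fixed order).
    """
    for seq in (a, b):
        if not seq:
            raise ValueError("cannot align an empty sequence")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    aligner = _aligner(config)
    alignment = aligner.align(a, b)[0]
    return float(alignment.score), (str(alignment[0]), str(alignment[1]))


def distance(aligned: tuple[str, str], correction: str = "p",
             config: Config | None = None) -> float:
    """p- or Poisson-corrected distance over aligned non-gap columns."""
    cfg = config or Config()
    row_a, row_b = aligned
    pairs = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"]
    if not pairs:
        raise ValueError("no aligned (non-gap) columns")
    p = sum(x != y for x, y in pairs) / len(pairs)
    if correction == "p":
        return p
    if correction == "poisson":
        cap = cfg["tree.poisson_cap"]
        if p >= 1.0 - 1e-12:
            return cap
        return min(cap, -np.log(1.0 - p))
    raise ValueError(f"unknown correction: {correction}")


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical NJ (Q criterion, Studier-Keppler updates).

    Negative branch lengths are clamped to 0; equal-Q joins are broken by the
    lexicographically smallest label pair (internal nodes are represented by
    the smallest leaf label beneath them).  The returned root is the final
    trifurcation (bifurcation for n = 3 resolved as a root with 3 children).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    reps: list[str] = list(dm.labels)
    d = dm.d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair = tuple(sorted((reps[i], reps[j])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _key, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(0.0, li), max(0.0, lj)
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_rep = min(reps[i], reps[j])
        new_row = np.array([
            0.5 * (d[i, k] + d[j, k] - d[i, j]) for k in range(m)
        ])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep],
                       new_row[keep][None, :]])
        d = np.hstack([d, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [new_rep]

    # terminal 3-node star: v_i = (d_ij + d_ik - d_jk) / 2
    (a, b, c) = (0, 1, 2)
    nodes[a].length = max(0.0, 0.5 * (d[a, b] + d[a, c] - d[b, c]))
    nodes[b].length = max(0.0, 0.5 * (d[a, b] + d[b, c] - d[a, c]))
    nodes[c].length = max(0.0, 0.5 * (d[a, c] + d[b, c] - d[a, b]))
    return TreeNode(children=list(nodes))


# ---------------------------------------------------------------------------
# Whole-batch trees

def family_tree(records, config: Config | None = None,
                region: str | None = None) -> TreeNode:
    """Similarity tree over annotated precursors.

    Each record is segmented and the configured comparison region extracted
    (``core`` = B+A concatenation, ``mature`` = everything after the signal);
    records lacking a framework are excluded with a warning.
    """
    from .cleavage import find_sites, predict_signal_cleavage
    from .cys_framework import find_core_framework
    from .domains import segment_domains

    cfg = config or Config()
    region = region or cfg["tree.region"]
    parts: list[tuple[str, str]] = []
    for rec in records:
        fw = find_core_framework(rec.residues, cfg)
        if fw is None:
            logger.warning("%s: no cysteine framework, excluded from tree", rec.id)
            continue
        try:
            signal = predict_signal_cleavage(rec.residues, rec.signal_cleavage, cfg)
            sites = find_sites(rec.residues, signal, fw, cfg)
            ann = segment_domains(rec.residues, signal, fw, sites, cfg)
        except ValueError as exc:
            logger.warning("%s: %s; excluded from tree", rec.id, exc)
            continue
        if region == "core":
            piece = ann.extract(rec.residues, "B") + ann.extract(rec.residues, "A")
        else:
            start = ann.intervals["signal"][1]
            piece = rec.residues[start:]
        parts.append((rec.id, piece))
    if len(parts) < 3:
        raise ValueError(f"need >=3 annotatable records, got {len(parts)}")
    labels = tuple(p[0] for p in parts)
    n = len(parts)
    d = np.zeros((n, n))
    correction = cfg["tree.correction"]
    for i in range(n):
        for j in range(i + 1, n):
            _score, rows = pairwise_align(parts[i][1], parts[j][1], cfg)
            d[i, j] = d[j, i] = distance(rows, correction, cfg)
    return neighbor_joining(DistanceMatrix(labels, d))


# ---------------------------------------------------------------------------
# Tree utilities (used by reports and tests)

def leaf_distances(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Patristic (path-length) distances between all leaf pairs."""
    dists: dict[tuple[str, str], float] = {}

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf():
            below = {node.label: 0.0}
        else:
            below = {}
            child_maps = [walk(c) for c in node.children]
            for i, map_a in enumerate(child_maps):
                for map_b in child_maps[i + 1:]:
                    for la, da in map_a.items():
                        for lb, db in map_b.items():
                            key = tuple(sorted((la, lb)))
                            dists[key] = da + db
                for label, dist in map_a.items():
                    below[label] = dist
        if node.length:
            below = {l: v + node.length for l, v in below.items()}
        return below

    walk(tree)
    return dists


def splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions (as the smaller-side leaf sets) of the tree."""
    all_leaves = frozenset(l.label for l in tree.leaves())
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.label])
        below = frozenset().union(*(walk(c) for c in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            comp = all_leaves - below
            side = below if (len(below), sorted(below)) <= (len(comp), sorted(comp)) else comp
            out.add(side)
        return below

    walk(tree)
    return out
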