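"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value by a method independent of the
implementation path it checks: exhaustive enumeration of alignments and of
cysteine sextets, nucleotide-by-nucleotide codon walking, and path-length
computation on explicitly constructed trees.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def enumerate_global_score(a: str, b: str, gap_open: int = 11,
                           gap_extend: int = 1) -> float:
    """Best global alignment score by exhaustive enumeration of all alignments.

    A length-L gap costs gap_open + L * gap_extend.  No memoization: every
    monotone alignment path is visited, so this is only usable for tiny inputs.
    """
    first = gap_open + gap_extend     # cost of opening plus the first position
    best = [float("-inf")]

    def rec(i: int, j: int, last: str, score: float) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + _BLOSUM62[a[i], b[j]])
        if i < len(a):  # gap in b
            cost = gap_extend if last == "X" else first
            rec(i + 1, j, "X", score - cost)
        if j < len(b):  # gap in a
            cost = gap_extend if last == "Y" else first
            rec(i, j + 1, "Y", score - cost)

    rec(0, 0, "", 0.0)
    return best[0]


def enumerate_framework(seq: str, bounds=None) -> tuple[int, ...] | None:
    """Max-score cysteine sextet by exhaustive enumeration over combinations.

    Bounds and scoring mirror the documented contract: A-motif gaps 2..6 and
    6..14 (modal 3 / 8), B-pair separation 8..16 (modal 12), C-span 5..80;
    ties prefer the most C-terminal A motif, then the smallest (cb1, cb2).
    """
    if bounds is None:
        bounds = dict(a=(2, 6), b=(6, 14), p=(8, 16), c=(5, 80),
                      a_mode=3, b_mode=8, p_mode=12)
    cys = [i for i, aa in enumerate(seq) if aa == "C"]
    best_key, best = None, None
    for combo in itertools.combinations(cys, 6):
        cb1, cb2, ca1, ca2, ca3, ca4 = combo
        if ca2 != ca1 + 1:
            continue
        gap_a, gap_b = ca3 - ca2 - 1, ca4 - ca3 - 1
        pair, span = cb2 - cb1, ca1 - cb2
        if not (bounds["a"][0] <= gap_a <= bounds["a"][1]):
            continue
        if not (bounds["b"][0] <= gap_b <= bounds["b"][1]):
            continue
        if not (bounds["p"][0] <= pair <= bounds["p"][1]):
            continue
        if not (bounds["c"][0] <= span <= bounds["c"][1]):
            continue
        score = ((gap_a == bounds["a_mode"]) + (gap_b == bounds["b_mode"])
                 + (pair == bounds["p_mode"]))
        key = (score, ca1, ca3, ca4, -cb1, -cb2)
        if best_key is None or key > best_key:
            best_key, best = key, combo
    return best


def codon_walk_phases(exon_seqs: list[str]) -> list[int]:
    """Intron phases by walking the concatenated CDS codon-by-codon.

    A buffer collects nucleotides; at each exon junction the number of
    nucleotides sitting in the split codon is the intron phase.
    """
    phases = []
    buffer = 0
    for exon in exon_seqs[:-1]:
        for _nt in exon:
            buffer += 1
            if buffer == 3:
                buffer = 0
        phases.append(buffer)
    return phases


# ---------------------------------------------------------------------------
# Random additive trees (for neighbor-joining recovery)

class SimpleNode:
    __slots__ = ("name", "edges")

    def __init__(self, name):
        self.name = name
        self.edges = []  # (other, length)


def random_additive_tree(rng, n_leaves: int):
    """Random unrooted binary tree with uniform branch lengths in [0.5, 2].

    Returns (leaf names, distance matrix dict, set of bipartitions).
    Built by sequential random edge attachment on an explicit graph.
    """
    leaves = [f"L{i}" for i in range(n_leaves)]
    nodes = {name: SimpleNode(name) for name in leaves[:3]}
    center = SimpleNode("I0")
    nodes["I0"] = center
    edges = []

    def connect(a, b, length):
        a.edges.append((b, length))
        b.edges.append((a, length))
        edges.append((a, b))

    for name in leaves[:3]:
        connect(nodes[name], center, float(rng.uniform(0.5, 2.0)))
    for k, name in enumerate(leaves[3:], 1):
        ea, eb = edges[rng.integers(len(edges))]
        ea.edges = [(o, l) for o, l in ea.edges if o is not eb]
        eb.edges = [(o, l) for o, l in eb.edges if o is not ea]
        edges.remove((ea, eb))
        mid = SimpleNode(f"I{k}")
        nodes[mid.name] = mid
        connect(ea, mid, float(rng.uniform(0.5, 2.0)))
        connect(mid, eb, float(rng.uniform(0.5, 2.0)))
        leaf = SimpleNode(name)
        nodes[name] = leaf
        connect(mid, leaf, float(rng.uniform(0.5, 2.0)))

    def path_lengths(start):
        dist, stack = {start.name: 0.0}, [start]
        while stack:
            node = stack.pop()
            for other, length in node.edges:
                if other.name not in dist:
                    dist[other.name] = dist[node.name] + length
                    stack.append(other)
        return dist

    dmat = {}
    for name in leaves:
        dist = path_lengths(nodes[name])
        for other in leaves:
            dmat[(name, other)] = dist[other]

    leafset = frozenset(leaves)
    bipartitions = set()
    for ea, eb in edges:
        # leaves on ea's side of the removed edge; blocking eb suffices in a tree
        seen = {ea.name, eb.name}
        stack = [ea]
        while stack:
            node = stack.pop()
            for other, _l in node.edges:
                if other.name not in seen:
                    seen.add(other.name)
                    stack.append(other)
        side = frozenset(n for n in (seen - {eb.name}) if n in leafset)
        if 1 < len(side) < n_leaves - 1:
            comp = leafset - side
            bipartitions.add(side if (len(side), sorted(side))
                             <= (len(comp), sorted(comp)) else comp)
    return leaves, dmat, bipartitions
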