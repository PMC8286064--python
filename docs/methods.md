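# Methods

This note documents the models and procedures implemented in `irpkit`, the
parameters that matter, the synthetic-data generator, and the numerical and
design choices that were genuinely open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## The precursor model

An irp precursor is modelled as an ordered partition

```
signal | [F] | B | C | A | [D] | [E]
```

with the insulin A- and B-chains carried by the A and B domains, the
connecting peptide by C, the IGF-type C-terminal extension by D (retained) and
E (furin-removed), and the dilp7-type N-terminal extension of the B chain by
F.  Present intervals are disjoint, ordered and cover the precursor exactly;
this partition property is asserted on every output.

### Cysteine framework search

The six core cysteines are found by scanning A-chain motifs
`C-C-x(a)-C-x(b)-C` from the C-terminus (the A chain is C-terminal in every
family modelled) and pairing them with two upstream B-chain cysteines.
Spacing bounds generalize the human insulin spacings (3, 8 and 12 residues,
with a connecting span of roughly 30):

| parameter | default | meaning |
|---|---|---|
| `framework.a_gap_min/max` | 2 / 6 | CA2–CA3 gap (modal 3) |
| `framework.b_gap_min/max` | 6 / 14 | CA3–CA4 gap (modal 8) |
| `framework.bpair_min/max` | 8 / 16 | CB1–CB2 separation (modal 12) |
| `framework.c_span_min/max` | 5 / 80 | CB2–CA1 span (the C region) |

Among all consistent assignments the one with the most spacings at their modal
values wins; ties prefer the most C-terminal A motif, and residual ties on the
B pair take the smallest (CB1, CB2).  For sequences up to 120 residues the
search provably equals exhaustive enumeration over all cysteine sextets (a
property test).  Absence of a framework is a result, not an error: such
records are reported as unclassified.

Bridge inference is purely combinatorial: six core cysteines give the
canonical pairing CA1–CA3, CA2–CB1, CA4–CB2; each complete extra pair adds one
bridge (assumed to bond together — the physical pairing of a fourth bridge is
deliberately flagged rather than asserted); an odd extra count reports the
paired subset with a warning.

### Cleavage rules

Furin sites use a two-tiered consensus: `[KR]-X-[KR]-R` (strong) and
`[KR]-X-X-R` (weak).  The weak tier exists because the two human IGF
precursors are processed at KSAR and KSER, which satisfy only the relaxed
form; a single-tier rule would be inconsistent with its own canonical
examples.  Proline at P1′ rejects a furin site.

Neuroendocrine (PC1/3, PC2) sites default to the `KR` motif (`RR`, `KK`, `RK`
and monobasic `R` are config-gated, default off, since only `KR` is the stated
consensus for these precursors).  A candidate is rejected when any
steric-hindrance exclusion fires, and the report carries every reason:

- `bulky-P1'` — P1′ in `{W,F,Y,I,L,V}` (`cleavage.bulky_p1prime`),
- `P1'-proline`,
- `pre-site-proline` — proline at P3 or P4,
- `disulfide-proximity` — a core-framework cysteine within
  `cleavage.disulfide_window` (default 3) residues of P1.

The bulky set, proline window and disulfide window operationalize qualitative
descriptions of convertase specificity; all are config keys.  Verdicts are
predictions: there is no certainty a predicted site is cleaved in vivo, which
is why the output is a reason trail rather than a probability.

The signal-peptide predictor is an explicit in-package heuristic (not a
re-implementation of any external predictor): candidate cleavage positions
p ∈ [15, 35] score +1 for a small residue (A/G/S/C/T) at p−1 and at p−3, plus
the mean Kyte–Doolittle hydropathy of the h-region window p−13..p−6 when it
reaches 1.5.  A known cleavage position supplied by the user always overrides
the heuristic.  This is adequate for the well-formed signal peptides the
generator emits; on real data a dedicated predictor should be preferred and
its result passed as the override.

### Segmentation details

B starts at the latest of the signal end, the boundary after the nearest
accepted upstream cleavage site, and `CB1 − b_lead` (`domains.b_lead`,
default 8 — the B-chain residues tolerated upstream of CB1).  A pre-B region
of at least `domains.f_min` = 15 residues becomes a distinct F domain,
otherwise it is merged into B; the threshold separates dilp7-type long
N-terminal extensions from ordinary B-chain leads, which the source material
distinguishes only qualitatively.  `two_chain` mode requires accepted sites on
*both* sides of C.  Downstream of CA4, the first accepted furin site splits D
from E; without one the whole extension is labelled D — deliberately
conservative, since invertebrate IGF D domains may be much larger than the
vertebrate ones and the D/E boundary cannot be asserted without a furin site.

## Classification

Features are aggregated deterministically (no thresholds at extraction time),
then a decision list fires in order of structural specificity:

1. **octinsulin** — extra cysteine pair at the octinsulin placement
   (`classify.octinsulin_extra_domains`, default B+D) and ≥1 accepted KR site;
2. **dilp7** — F domain ≥ `f_min`, F identity ≥ `classify.f_identity_min`
   (0.4) when references are supplied, two-chain;
3. **IGF** — tail ≥ `classify.tail_min` (25) residues with charged fraction ≥
   `classify.charged_min` (0.3), single-chain;
4. **GSS** — the residual two-chain class: short tail, no F domain, no extra
   cysteine *pair*;
5. **multinsulin** — two-chain, no F domain, with the multinsulin extra-pair
   placement (C domain) or the multinsulin gene signature.

When both residual rules fire, the gene signature decides; without gene
evidence the call is GSS with multinsulin as runner-up at low confidence.
Thresholds were calibrated on the generator templates, since the source
families are contrasted only qualitatively.

One deliberate choice: the GSS rule tolerates a single *unpaired* extra
cysteine (`classify.gss_max_extra_cys` = 1).  An unpaired cysteine cannot form
a disulfide bridge, so it does not contradict the six-cysteine/three-bridge
architecture; requiring exactly zero would make the residual class brittle to
a single substitution creating a stray cysteine.

Confidence is `high` only with ≥2 concordant evidence items and no anomaly
(unpaired extra cysteine, or a B domain longer than `classify.b_max` = 30 —
B chains are short throughout the superfamily, so an oversized B usually means
an upstream boundary slipped).  The classifier is a pure function of the
feature vector.

## Gene structure

Intron phase is the coding offset modulo 3 (phase 1 = after the first
nucleotide of a codon); the interrupted residue is `offset div 3`, looked up
in the domain intervals.  Signatures: a phase-1 intron in C is required for
any call (it is shared by all five families and is the only coding intron of
GSS and octinsulin genes — hence those two share one token); a phase-2 intron
marks the dilp7 lineage; a second phase-1 intron on top of that marks
multinsulin; a phase-0 intron in the last `genes.igf_terminal_frac` = 25% of
the CDS marks IGF ("near the end of the coding sequence" needed a number; the
last quarter cleanly separates the generator's placements).  The optional IGF
phase-1 intron near the transcription start is not required — it is reported
for only some IGF genes — and the generator omits it.

## Microsynteny

Gaps are measured end-to-start between coding regions (overlapping loci get
gap 0) and reported in kb.  The joining threshold `synteny.max_gap` defaults
to 1 Mb, separating "next to one another" distances (tens of kb) from the
6–28 Mb distances at which GSS genes sit from the main cluster.  Strand is
recorded and reported but does not affect clustering.  The conserved
arrangement check asks specifically whether an IGF locus lies strictly between
an octinsulin (or gonadulin) locus and a dilp7 locus.

## Similarity trees

Pairwise global alignment uses BLOSUM62 with affine gaps (open 11, extend 1;
a length-L gap costs 11 + L).  Distances are p-distances by default
(`tree.correction`), with a Poisson option capped at `tree.poisson_cap` = 5
as p → 1.  Neighbor joining is the canonical Q-criterion/Studier–Keppler
algorithm with negative branch lengths clamped to zero and equal-Q joins
broken by the lexicographically smallest label pair, making the whole tree a
deterministic function of its inputs.  The default comparison region is the
concatenated B+A core: the D/E extensions are conserved only between closely
related species and would otherwise dominate the distances.  These trees
illustrate similarity, not phylogeny; no support values are computed.

## Receptor annotation

TM segments: centered 19-residue Kyte–Doolittle windows above 1.6, runs ≥8
residues after merging runs separated by <3 — classical hydropathy-scan
settings, all config keys.  LDLa repeats match the six-cysteine module
`C-x(2,7)-C-x(3,9)-C-x(4,10)-C-x(2,8)-C-x(5,14)-C` and additionally require
≥3 acidic residues in an 8-residue window within 12 residues of the match (the
calcium-binding acidic cluster); matching is greedy left-to-right, shortest
match per anchor.  LRRs match `J-x-x-J-x-J-x-x-[NC]-x-J` with J ∈ {L,I,V,F},
collapsing hits closer than 20 residues.  Both patterns are regex stand-ins
for profile models — adequate for counting well-formed repeats, not for
discovering degenerate ones.  Architecture calls: `GRL101_like` = 7 TM, ≥6
LDLa, ≥3 LRR; `single_LDLa_LGR_like` = 7 TM, 1–2 LDLa, ≥3 LRR.

## The synthetic-data generator

The generator emulates the *structural contrasts* between the five families,
not real ambulacrarian sequence composition.  Each template carries: a
15-residue signal peptide with a hydrophobic h-region and small residues at
−3/−1; family-specific B and A cores at the modal spacings; planted `KR` sites
in clean contexts flanking C (two-chain families); the octinsulin extra pair
at B-start + post-CA4 and the multinsulin pair in C (the exact published
positions are figure-only, so these placements are generator conventions,
kept as config-visible defaults); a 25-residue F domain for dilp7; a
40-residue charged D+E tail with a weak furin site for IGF.  Segment lengths
(signal 15, C region ~20, IGF tail 40) sit inside the ranges depicted for
real family members.  The B/A core interiors encode the lineage structure —
GSS cores resemble IGF, multinsulin cores resemble dilp7, octinsulin stands
apart — so similarity trees over generator batches have a defined expected
grouping.

Gene models reverse-translate the template protein (seeded codon choice, plus
stop) and cut the CDS at the planted intron positions: phase-1 in C for every
family; phase-2 near the F/B boundary for dilp7; the same plus a phase-1 in B
(four coding exons) for multinsulin; phase-1 in C plus a late phase-0 for
IGF.  The emitted CDS translates exactly to the emitted precursor, and the
genomic exons spliced back together reconstruct the CDS.

Point mutations are applied per eligible position at the requested rate,
substituting uniformly among the 19 alternatives.  Defining marks — core and
extra cysteines, planted site motifs with their P4..P1′ contexts, the signal
c-region — are never mutated: noise tests whether thresholds tolerate
perturbation, not whether destroying a mark destroys the call.  A separate
`ablate` mode removes one mark at a time for negative tests.  Everything is a
pure function of (seed, parameters); outputs are byte-identical across runs.

**What passing tests do and do not show.**  The generator's sequences are
idealized: real precursors have variable signal peptides, degenerate cleavage
contexts, lineage-specific indels and compositional biases that the templates
do not model.  Recovery rates on generator batches therefore demonstrate the
internal consistency and noise robustness of the rules, not their accuracy on
real proteomes.

## Numerical choices and degenerate inputs

- All internal coordinates are 0-based half-open; GFF3/TSV serializations are
  1-based inclusive; round trips are identity.
- `X` is a legal unknown residue, scored 0 on the hydropathy scale and never
  matched by the cysteine or repeat patterns; `*` stops are stripped on input.
- Batch annotation isolates per-record failures (a corpus with broken records
  must not abort); the report always has one row per input.
- Tie-breaks everywhere are documented and deterministic (framework search,
  alignment traceback, NJ joins, signal-position ties to the smallest p).
- Problem sizes in the test suite (50 noise-free and 200 noisy replicates per
  family, 200 random 6-leaf trees, 1,000 random exon partitions, a 50-leaf
  similarity tree) were chosen to make sampling noise negligible relative to
  the asserted margins while keeping the whole suite fast.

## Known limitations

- The signal heuristic occasionally (a few percent of heavily mutated
  sequences) prefers a position a few residues downstream of the true
  cleavage; such records surface as isolated failures, not silent errors.
- Physical disulfide connectivity of a fourth bridge is flagged, never
  asserted.
- Copy-number expansion and exon-chimerism of multinsulins, alternative
  splicing, splice-site validation (GT–AG), and receptor–ligand pairing are
  out of scope.
- The repeat patterns count canonical LDLa/LRR units; profile-HMM scanning
  would be needed for degenerate repeats in real receptors.
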