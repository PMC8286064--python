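# irpkit

Structural annotation of **insulin/IGF-related peptide (irp) precursors**, their
genes, and their candidate leucine-rich-repeat GPCR (LGR) receptors.

Insulin-superfamily peptides are notoriously variable in primary sequence, yet
share a rigid structural scaffold: six core cysteines forming three disulfide
bridges, a two- or single-chain architecture produced by prohormone-convertase
processing, and family-specific marks such as extra cysteine pairs, a conserved
N-terminal **F domain**, or a long charged C-terminal extension.  `irpkit`
implements, as a tested and reusable pipeline, the comparative workflow used to
characterize the five irp families of echinoderms and hemichordates — **IGF**,
**GSS** (gonad stimulating substance), **octinsulin**, **dilp7 orthologs** and
**multinsulins** — together with the gene-structure and microsynteny
diagnostics that support those family assignments.  It is aimed at researchers
annotating invertebrate peptide-hormone repertoires from genome or
transcriptome assemblies.

## What it does

- **Cysteine framework** — locates the core motif
  `CB1 – x(8..16) – CB2 … CA1 CA2 – x(2..6) – CA3 – x(6..14) – CA4`
  (human-insulin modal spacings 12/3/8), classifies extra cysteines by domain,
  and infers the bridge count (3 for six-cysteine peptides, 4 when an extra
  pair is present; pairing `CA1–CA3, CA2–CB1, CA4–CB2`).
- **Cleavage prediction** — signal-peptide heuristic ((−3,−1) small-residue
  rule + Kyte–Doolittle h-region hydropathy, user override always wins), a
  two-tiered furin rule (`[KR]-X-[KR]-R` strong, `[KR]-X-X-R` weak — the tier
  that covers the human IGF sites KSAR/KSER), and neuroendocrine `KR` sites
  with steric-hindrance exclusions (bulky or proline P1′, pre-site proline,
  disulfide proximity), each site reported with its full reason trail.
- **Domain segmentation** — signal / F / B / C / A / D / E intervals (a strict
  ordered partition of the precursor), tail charge features, F-domain identity
  against references.
- **Family classification** — an evidence-weighted decision list over the
  extracted features, with confidence grading and a gene-structure tie-break.
- **Gene structure** — intron phases from GFF3 CDS exons (`phase = coding
  offset mod 3`), intron-to-domain mapping, and the family signatures: a
  phase-1 intron in the C domain in all families (the *only* intron of GSS and
  octinsulin genes), a shared phase-2 intron in dilp7/multinsulin genes, an
  additional phase-1 intron (4 coding exons) in multinsulins, a late phase-0
  intron in IGF genes.
- **Microsynteny** — gap-threshold clustering of locus tables, detection of the
  conserved octinsulin–IGF–dilp7 arrangement with IGF in the middle, and
  cross-species composition comparison.
- **Similarity trees** — BLOSUM62 global alignments (affine gaps 11/1) of the
  B+A cores, p or Poisson distances, canonical neighbor joining.  These are
  deliberately *similarity* illustrations, not phylogenies: the superfamily's
  sequence variability defeats the assumptions of likelihood methods, so a
  simple deterministic distance method is used and documented as such.
- **Receptor annotation** — 7-TM detection by Kyte–Doolittle scanning, LDLa
  (six-cysteine module + acidic cluster) and LRR consensus repeats, and the
  architecture calls `GRL101_like` (many LDLa + LRRs + 7 TM) vs
  `single_LDLa_LGR_like` (the gonadulin/dilp7-receptor layout).
- **Synthetic data** — a deterministic generator of family-templated
  precursors, matching gene models (CDS translates exactly to the emitted
  precursor), synteny layouts and receptor presets, so the whole pipeline is
  testable without downloading any genome.

## Worked example

```bash
irpkit fixtures --seed 1 --out demo
irpkit annotate demo/precursors.fasta --gff3 demo/genes.gff3 --out demo/report.tsv
```

First record of each family from `demo/report.tsv`:

```
             id  n_extra_cys  n_bridges   chain_mode  tail_len  f_len    gene_signature       label confidence
        IGF_1_0            0          3 single_chain        40      0               IGF         IGF       high
        GSS_1_0            0          3    two_chain         0      0 GSS_or_octinsulin         GSS       high
 octinsulin_1_0            2          4    two_chain         4      0 GSS_or_octinsulin  octinsulin       high
      dilp7_1_0            0          3    two_chain         0     25             dilp7       dilp7       high
multinsulin_1_0            2          4    two_chain         0      0       multinsulin multinsulin       high
```

Reading the rows: the IGF precursor is single-chain with a 40-residue charged
D+E tail; GSS is the residual two-chain six-cysteine peptide; octinsulin
carries the extra cysteine pair (4 bridges); the dilp7 ortholog shows its
25-residue F domain; the multinsulin is dilp7-like without the F domain but
with its own extra cysteine pair.  The `gene_signature` column shows the
intron-phase diagnostics (GSS and octinsulin genes are indistinguishable by
gene structure — both have only the phase-1 C-domain intron).

Synteny and receptors:

```bash
irpkit synteny demo/loci_clustered.tsv --out demo/clusters.tsv
irpkit receptor demo/receptors.fasta --out demo/receptors.tsv
```

```
cluster1  chr1  oct1(octinsulin+),igf1(IGF-),igf2(IGF-),dilp7_1(dilp7-)  20.152,44.894,46.331  triplet_with_IGF_middle
cluster2  chr1  gss1(GSS+)    other

id                 n_tm  n_lrr  n_ldla  architecture_call
GRL101_1           7     6      12      GRL101_like
single_LDLa_LGR_1  7     5      1       single_LDLa_LGR_like
```

The four-gene cluster shows the conserved arrangement with IGF between
octinsulin and dilp7 (inter-gene gaps in kb); the GSS gene sits 6 Mb away as a
singleton.  The GRL101-type receptor is recognized by its 12 LDLa and 6 LRR
repeats ahead of the seven transmembrane helices.

All thresholds live in one flat config (`irpkit.config.DEFAULTS`) and can be
overridden from a plain-text file via `--config`; see `docs/methods.md` for
what each parameter means and how defaults were chosen.

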