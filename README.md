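# mitocensus

A characterization toolkit for plant organelle genomes, built around the
analyses typically reported when a new plant mitochondrial genome
(mitogenome) is described: base composition, microsatellite (SSR) and
maximal-repeat censuses, relative synonymous codon usage (RSCU), approximate
Ka/Ks selection estimates, detection of chloroplast-derived transfer
segments (MTPTs), core/variable/specific pan-mitogenome constitution with
accumulation curves, and a distance-based phylogeny. It is aimed at
researchers assembling and annotating organelle genomes who want these
standard analyses as reproducible, scriptable library calls instead of a
patchwork of web servers, plus a synthetic-genome simulator with planted,
truth-tabled features so every stage can be validated end to end without
any downloads.

Plant mitogenomes are large (hundreds of kb), repeat-rich and structurally
fluid, which is exactly why these censuses matter: large repeats mediate
recombination, SSRs supply markers, plastid-derived tracts record organelle
gene transfer, and the pan/core decomposition separates the conserved gene
backbone from lineage-specific "dumping ground" sequence.

## Methods at a glance

- **SSRs** — maximal perfect tandems of 1–6 bp motifs above per-unit copy
  thresholds (defaults: 10/6/5/5/5/5 for mono- through hexamers, the MISA
  convention). Motifs are reported at their smallest period and grouped
  into canonical rotation/complement classes (`A/T`, `AG/CT`, ...).
- **Maximal repeats** — exhaustive enumeration of exact repeat pairs
  ≥ 30 bp, forward (F) and palindromic/reverse-complement (P): two arms
  that cannot be extended one base at either end without breaking the
  match.
- **RSCU** — for codon *c* in a synonymous family of size *k* with family
  total *n*: `RSCU(c) = count(c) · k / n`; an unbiased family averages to
  exactly 1. Stops form a 3-member family (TAA/TAG/TGA), universal code.
- **Ka/Ks (LWL & MLWL)** — codon positions are classed 0-, 2- or 4-fold
  degenerate; transition/transversion proportions P_i, Q_i per class get
  Kimura two-parameter corrections A_i = ½ln(1/(1−2P_i−Q_i)) −
  ¼ln(1/(1−2Q_i)), B_i = ½ln(1/(1−2Q_i)), combined as
  `Ks = (L2·A2 + L4·(A4+B4)) / (L2/3 + L4)` and
  `Ka = (L0·(A0+B0) + L2·B2) / (L0 + 2·L2/3)`. MLWL replaces the fixed 1/3
  synonymous share of 2-fold sites with κ/(κ+2), κ estimated from the
  4-fold sites. Multi-difference codons are decomposed over stop-free
  mutational pathways, weighted equally.
- **Transfer segments** — a seed–chain–extend local aligner (exact word
  anchors, collinear chaining, affine-gap closure, X-drop ends; match +1,
  mismatch −2, gap open −5, extend −2) with a Karlin–Altschul style
  E-value; transfer calls default to ≥ 93% identity, ≥ 300 bp, E ≤ 1e−5.
- **Constitution** — per-base homology counts across N genomes label every
  base `core` (present in all), `specific` (one genome only) or `variable`;
  pan/core accumulation curves over random genome orderings count each
  homologous block family once.
- **Phylogeny** — p/JC69/K2P distances, Saitou–Nei neighbor-joining and
  column-bootstrap supports; an alignment-free 8-mer cosine distance serves
  for whole unaligned mitogenomes. This is a deliberate distance-based
  stand-in for likelihood tree searches.

## Worked example

Simulate a 20 kb circular genome with planted features, then census it:

```bash
$ mitocensus simulate --length 20000 --gc 0.44 --seed 11 \
    --ssr A:12 --ssr AG:7 --repeat 45:F --repeat 40:P --out demo
wrote demo.fasta and demo.truth.json

$ mitocensus ssr demo.fasta
id	ssr_nr	type	motif	size	start	end
synth_1000014	1	p2	(AG)7	14	2600	2613
synth_1000014	2	p1	(A)12	12	2704	2715

$ mitocensus repeats demo.fasta
arm_len	pos1	pos2	orientation
45	6783	14865	F
40	835	17483	P
```

Both planted SSRs are recovered with their exact motifs, copy numbers and
coordinates ((AG)7 = 14 bp at 1-based 2600–2613), and the two planted
repeat pairs come back with the right arm lengths, positions and
orientations — `F` meaning both arms on the same strand, `P` meaning the
second arm is the reverse complement of the first. `demo.truth.json` holds
the generator's planted coordinates for independent comparison. The same
stages run on real data via `mitocensus census --genbank record.gb --cp
chloroplast.fasta --out outdir`, which writes the full report bundle
(composition.tsv, ssr.tsv, repeats.tsv, codon_rscu.tsv, transfers.tsv,
constitution.bed, accumulation.tsv, tree.nwk, manifest.json).

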