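# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one defensible option
existed.

## Coordinates and formats

All internal coordinates are 0-based half-open; conversions to the 1-based
inclusive conventions of GenBank and GFF3 happen only in `genome_io` at the
format boundary, so off-by-one risk is confined to two functions that are
round-trip tested. Features wrapping the origin of a circular molecule are
stored as two ordinary intervals with a wrap flag rather than modular
coordinates, keeping interval arithmetic standard. `N` is a legal sequence
symbol but is excluded from GC denominators, breaks SSR runs and repeat
matches, and codons containing it are skipped (and counted) in codon
statistics. GenBank parsing accepts gene- and product-level features; the
census counts features by their kind (gene/CDS/tRNA/rRNA), assigns
`copy_index` 1, 2, ... to duplicated names in file order, and deliberately
preserves duplicate annotations rather than collapsing them, so curation
artifacts stay visible in the output.

## Composition and codon usage

The genic/intergenic partition is the per-base union of a configurable
feature set (default: CDS only, i.e. protein-coding genes; a caller can
widen it to all genes). Overlapping annotations are counted once, so genic
plus intergenic lengths always equal the genome length — an invariant the
tests enforce on every input. Codon counting uses the universal genetic
code (NCBI table 1, appropriate for plant mitochondria; the table id is a
parameter), includes stop codons by default, counts duplicated gene copies
per copy, and truncates a CDS whose length is not a multiple of three with
a logged warning rather than failing — curated organelle annotations
occasionally contain pseudogene fragments. RSCU of a codon is its count
divided by its family mean; a family with zero observations is defined as
all-zero rather than undefined.

## SSR detection

A locus is a maximal perfect tandem of a primitive (smallest-period) motif
of 1–6 bp meeting the per-unit-length minimum copy numbers
{1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}. These are the MISA defaults; they
are exposed as parameters because published censuses depend on them and
rarely state them. The locus spans whole motif copies
(`end − start = unit_len · copies`); a trailing partial unit never extends
a locus. Overlapping candidates of the same period are resolved by keeping
the longer locus. Circular scanning extends the window past the origin by
one base less than the largest threshold span and de-duplicates loci by
canonical start, making detection invariant to rotation of the record.
Compound-SSR annotation (MISA's interrupted pairs) is intentionally not
implemented: the summaries here report simple loci only.

## Maximal repeat pairs

The contract is exhaustive enumeration of maximal exact pairs (forward and
reverse-complement) above a minimum arm length, with symmetric duplicates
reported once. The implementation seeds on shared `min_len`-mers, keeps
only seed pairs whose preceding characters differ (each maximal pair has
exactly one such left end, so enumeration is complete and duplicate-free),
and extends rightward. Work scales with repeat content rather than genome
length squared; an O(n²) diagonal-scan brute force lives in the test suite
as the independent oracle and the two agree exactly on randomized and
planted fixtures. Tandem, self-overlapping pairs (second arm starting
inside the first) are kept, matching maximal-pair semantics. A word that is
its own reverse complement pairing with itself at the same position is
excluded. The guard `min_len ≥ 8` exists because below that the output on
random sequence explodes combinatorially.

## Local alignment, transfers, E-values

`local_align_segments` is seed–chain–extend: exact anchors of `word_size`
(default 7) on both strands, merged into exact runs per diagonal; runs two
bases longer than the word are clustered within a 30-diagonal band and
300 bp join gap; a max-weight collinear chain (gap-penalized at 0.6 per
unseeded base) is closed with an affine-gap global alignment between
consecutive runs and extended ungapped at both ends under an X-drop of 20.
Scoring is match +1, mismatch −2, gap open −5, gap extend −2. Significance
uses E = K·m·n·e^(−λS) with the standard ungapped nucleotide parameters
for +1/−2 (λ = 1.33, K = 0.621); this is approximate for gapped segments
and is documented as such — the default threshold (E ≤ 1e−5) sits many
orders of magnitude away from the scores of real segments, so the
approximation does not move calls. Filtered candidates are reduced to a
non-overlapping (on the query) best-scoring set, greedy by score with
leftmost-start tie-break, allowing up to 25% overlap to tolerate boundary
jitter. Agreement with an exact Smith–Waterman oracle (Biopython's local
aligner under the same scoring) is tested to ±2 bp on coordinates and
±0.01 on identity. Transfer detection is this aligner with the
plastid-transfer defaults: identity ≥ 0.93, length ≥ 300 bp, E ≤ 1e−5,
reported in mitogenome order with a count/total-length summary.

## Constitution and accumulation curves

Homology evidence — either MAF blocks from an external whole-genome
aligner or the internal all-pairs aligner — is rasterized into per-base
boolean coverage of each genome by each other genome. A base is `core`
when all N genomes cover it, `specific` when only its own genome does,
`variable` otherwise; interval merging is exact, and the three labels
partition every genome by construction. For the accumulation curves,
genome orderings are sampled (default up to 500 permutations, seeded); for
a prefix of k genomes the core size is measured on the first genome of the
ordering (each core family counted once, in reference coordinates) and the
pan size adds only the bases of each new genome not already covered by an
earlier one — the "homologous sequence counted once" rule as per-base
de-duplication. Mean, min and max over orderings are reported per k. Pan
is non-decreasing and core non-increasing within every ordering; the tests
assert both, plus recovery of planted pan/core sizes. GC by class is
computed over the concatenated bases per label per genome; empty classes
are omitted rather than reported as zero.

## Ka/Ks: LWL and MLWL

Sites: a codon position is 4-fold degenerate if all three point changes
are synonymous, 0-fold if none, otherwise 2-fold; a change into a stop is
never synonymous, and stop-containing or gapped codon columns are dropped
from the alignment (counted in the result). L_i averages the two
sequences' site classes. Differences: a codon pair differing at d
positions is decomposed over all d! orderings in both directions;
pathways through stop codons are excluded entirely, remaining pathways are
weighted equally, and each step is tallied as a transition or transversion
in the degeneracy class of the changed position of the codon the step
starts from. If every pathway hits a stop the pair is dropped with a log
entry. Per class, P_i and Q_i receive the Kimura two-parameter correction;
LWL combines them with the fixed 1/3 synonymous share of 2-fold sites.

MLWL replaces that share with κ/(κ+2), where κ = 2·A4/B4 estimated at the
4-fold sites (pooled classes as fallback, then κ = 2; floored at 0.5 to
avoid degenerate weighting). The irregular isoleucine/arginine positions —
where the synonymous change is a transversion or more than one change is
synonymous (third positions of ATT/ATC/ATA, first of AGA/AGG/CGA/CGG) —
are weighted by their own synonymous transition/transversion make-up,
(κ·ts_syn + tv_syn)/(κ+2). A consequence worth stating plainly: MLWL with
κ forced to 1 reproduces LWL exactly on sequences free of those irregular
codons, and differs slightly on sequences containing them, because LWL's
canonical 1/3 mis-weights exactly those sites — that is the point of the
modification. Saturation (a non-positive logarithm argument in any needed
class) flags the result and leaves Ka/Ks undefined; Ks = 0 with Ka > 0 is
flagged infinite. For unaligned input a codon-aware pre-aligner (global
alignment of the translations, back-mapped to codons, BLOSUM62) is
provided; externally aligned CDS are accepted as-is.

Parameter recovery under the simulator (K2P with an acceptance probability
ω for amino-acid-changing substitutions): the median MLWL estimate over
100 replicates of 300 codons at per-site rate 0.08 lands within 20% of the
true ω for ω ∈ {0.2, 1.0}; this is asserted in the acceptance suite and
recomputed by the acceptance script.

## Phylogeny

Distances: p, JC69 (−¾ln(1−4p/3)) and K2P (−½ln(1−2P−Q) − ¼ln(1−2Q)),
with gap/ambiguous columns removed pairwise and explicit saturation
errors. Neighbor-joining is the standard Saitou–Nei agglomeration with the
Q criterion, deterministic lexicographic tie-breaking, and negative branch
lengths clamped to zero with the deficit shifted to the sibling. NJ
recovers the generating topology from any additive matrix (tested on
random 6-taxon trees and cross-checked against dendropy's implementation).
Bootstrap resamples alignment columns with replacement; supports are the
percentage of replicate trees containing each internal split of the
point-estimate tree, and a replicate pair that saturates falls back to the
p-distance so replicates never abort. For whole unaligned mitogenomes an
8-mer cosine distance is provided as an alignment-free fallback. All of
this is an explicit desk-scale stand-in for maximum-likelihood tree
searches: it checks topology-level claims (sister relationships, clade
supports), not branch-length inference under a substitution model.

## Synthetic data: what it emulates, what it does not

`make_genome` draws i.i.d. bases at a requested GC (1 kb–10 Mb);
`clean_background` rejection-samples (cap 50 tries) until no accidental
SSR or ≥30 bp repeat survives, so on planted genomes every detection is
either truth or a bug. `plant_features` writes SSR tracts, repeat pairs,
valid ORFs with specified codon frequencies, and donor segments mutated to
a target identity, at recorded non-overlapping coordinates, with flanking
guard bases so planted features are exactly maximal. `evolve_genome`
applies per-site K2P substitutions (transition probability κ/(κ+2)),
optional purifying selection in CDS regions (nonsynonymous changes
accepted with probability ω) and optional short indels.
`make_genome_family` evolves a root along a Newick tree and applies
recorded lineage-specific insertions/deletions to create known
core/variable/specific structure. Everything is bit-reproducible given
(seed, spec), and every planted feature is emitted in a JSON truth table.

What this does not emulate: real mitogenome repeat-mediated recombination
and substoichiometric isoforms, mutation-rate heterogeneity along the
genome, realistic codon usage bias of organelle genes, and sequencing or
assembly error. Passing the closed-loop tests therefore demonstrates
correctness of the detectors and estimators under their stated models, not
robustness to every artifact of real assemblies; the GenBank-driven
integration path exists for the latter.

## Problem sizes and defaults in the acceptance script

The acceptance script (`scripts/acceptance.py`) uses 12–30 kb backgrounds,
a 100 kb genome for GC calibration, 4-genome families of 8 kb with a
1.5 kb planted specific tract, 200 accumulation permutations, 100
replicates of 300 codons for ω recovery, ten 5-taxon families for topology
recovery and 200 bootstrap replicates. These sizes were chosen as the
smallest at which each measured quantity is stable to well within its
natural sampling variation on a single CPU; all randomness derives from
the `--seed` argument.

## Known limitations

- The repeat and SSR censuses of any published genome depend on the exact
  tool conventions used there (seed settings, mismatch allowances,
  thresholds); this package fixes one documented convention (exact
  matches, MISA default thresholds) and exposes the knobs.
- The E-value is ungapped-parameter Karlin–Altschul applied to gapped
  scores; ranking is sound, absolute values near a loose threshold are not.
- MLWL's κ estimator degrades at very low divergence (few 4-fold
  differences); the floor and fallbacks keep it defined but crude there.
- The aligner's non-overlap selection can split one biological segment at
  a long indel into two reported segments; counts on indel-rich pairs are
  convention-dependent.
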