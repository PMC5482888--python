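# Methods

## Scope and data model

The package analyses one annotated circular mitochondrial genome at a
time (plus cohorts for tabular comparison). The central objects are
`GeneFeature` — a named region with 1-based inclusive coordinates on the
deposited (J) strand, an orientation (J / N / unoriented for the control
region), and optional anticodon / start / stop metadata — and
`MitogenomeRecord`, the ordered annotation plus optional sequence. The
controlled gene vocabulary is the canonical metazoan 37-gene complement
(13 PCGs, 22 tRNAs with S1/S2 and L1/L2 isoacceptors kept distinct, two
rRNAs) plus `CR`; aliases (`COI`, `tRNA-Ser(AGN)`, `D-loop`, …) are
resolved case-insensitively on input.

### Coordinate conventions

Coordinates are 1-based inclusive on both ends, so a feature's size is
`end − start + 1`; this reproduces every published gene size (e.g.
rrnL 11,277–12,612 → 1336 bp). A feature may wrap the origin
(`end < start`); its length is then `L − start + 1 + end`. The intergenic
spacer between consecutive features is `start(next) − end(prev) − 1`,
negative for overlaps (atp8/atp6 share 7 bp), and taken modulo the circle
for the pair that wraps the origin. Spacers are always recomputed from
coordinates rather than trusted from input tables, since printed
intergenic columns are a frequent source of transcription errors.
`validate_annotation` returns findings rather than raising: out-of-range
coordinates and duplicate names are errors; missing members of the
37-gene complement and spacers above a threshold (default 50 bp — long
spacers in rearranged mitogenomes are candidate pseudogene remnants of a
translocated tRNA) are warnings.

## Composition and skew

AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C). Both are scale-free
(identical on counts or percentages), bounded by [−1, 1], and exactly
antisymmetric under reverse complementation — a property the test suite
checks on random sequences. Region profiles concatenate the member genes
of each class. **Strand convention:** by default each gene contributes
its mRNA-sense (annotated-strand) sequence; a `strand="J"` switch forces
the deposited strand for every gene. Published per-region tables rarely
state which convention they used, so both are provided and the choice is
surfaced in the API rather than silently fixed. The whole-genome profile
is always the J strand. For report parity with the literature,
percentages are rounded to 1 decimal and skews to 3; internal values keep
full precision. Note that a skew recomputed from rounded percentages can
differ from the full-precision value by about ±0.002 (e.g. a genome GC
skew of −0.226 from rounded percentages versus −0.228 at full precision),
so comparisons against printed values should use printed percentages.

## Codon usage and RSCU

The genetic code is NCBI translation table 5 (invertebrate
mitochondrial), taken from Biopython's code tables: an 8-codon serine
family including AGA/AGG, UGA read as tryptophan, AUA as methionine, and
a 2-codon stop family {UAA, UAG} which receives RSCU like any other
family. CDS extraction reverse-complements N-strand genes; codons are
read in frame from position 1 and a trailing 1–2 nt remainder — the
incomplete stop completed to UAA by polyadenylation — is excluded from
the counts. RSCU(c) = count(c) · |F| / N_F for family F with total
N_F > 0, zero otherwise; within every non-empty family the values sum to
the family size. The full published 64-codon table for the reference
genome is reproduced from its printed counts at 2-decimal precision (a
regression fixture in the test suite). The frame is never re-inferred
from sequence content; annotation is authoritative.

## Gene-order rearrangement analysis

Gene orders are signed circular permutations: + for the majority strand,
− for the minority strand, the control region unsigned. Equality is
rotation-invariant. Each order induces a set of signed adjacencies, with
(a, b) canonically identified with (−b, −a); the breakpoint distance
between two orders over the same gene set is the number of adjacencies of
one absent from the other — symmetric, zero exactly when the orders are
equal up to rotation (or to reading the whole circle from the other
strand, which preserves every adjacency by construction).

The built-in reference is the pancrustacean ground pattern, the inferred
ancestral arrangement conventionally used as the baseline in crustacean
mitogenomics. The event classifier is deliberately greedy and
conservative, in this order: sign-only inversions, adjacent swaps
(p·x·y·q → p·y·x·q with per-gene signs kept), then single-gene
translocations (g moved between two genes adjacent once g is removed).
The inferred events are replayed on the reference; if the replay does not
reproduce the observed order, the remaining out-of-place genes are
reported as a single `unclassified` event rather than forced into a
duplication/loss narrative — tandem-duplication–random-loss scenarios are
mechanistic hypotheses, not something a pairwise order diff can
establish. On the reference genome this yields exactly two events versus
the ground pattern: the trnI–trnQ adjacent swap and the translocation of
trnH to between trnE and trnF, with a breakpoint distance of 6.

## Synthetic mitogenome generator

`GenomeSpec` fixes gene order, per-gene lengths, spacers (negative =
overlap), per-region base-composition targets and codon-usage weights;
`GenomeSpec.ku589292_like()` fills all of these with the published
reference values, so one call produces a realistic 15,706 bp record with
38 features at the published coordinates. Protein genes are drawn
codon-wise from the weights with stop codons excluded internally, the
annotated start codon forced, and the tail determined by length mod 3
(complete stop / TA / T). tRNA, rRNA and control-region sequences are
i.i.d. per-base draws from their region's target composition; unassigned
spacer positions are filled from the control-region composition. Where a
negative spacer makes two genes overlap, the downstream gene's sequence
takes precedence over the shared bases (mirroring real shared-frame
overlaps), so the upstream gene's annotated stop codon need not appear
literally in the assembled sequence. A single `numpy` generator seeded
from the spec drives everything; the same seed yields byte-identical
output.

What the generator does *not* emulate: repeat structure and secondary
structure in non-coding DNA, rate heterogeneity, indels, and — most
importantly — strand-asymmetric mutation pressure. Because genes are
simulated on their sense strands from symmetric per-region targets, the
whole-genome J-strand GC skew of a synthetic genome sits near zero rather
than at the strongly negative values real crab mitogenomes show; A+T
content, which is strand-symmetric, is recovered faithfully (75.7 ± 1
point at genome scale). Passing recovery tests therefore demonstrates
correctness of the statistics and plumbing, not realism of the
evolutionary process.

Alignments for the phylogeny stage are evolved along a user-supplied
binary tree under Jukes–Cantor (branch lengths in expected
substitutions/site), chosen because its closed form
p = ¾(1 − e^(−4b/3)) lets the simulator itself be validated against
theory; the two-taxon check at 10⁵ sites agrees to ±0.01.

## Phylogenetic support stage

The stage stands in for the topology-and-support role of full ML/Bayesian
phylogenomics, and the documentation of every entry point says so; it is
not an inference engine for real data. Components: supermatrix
concatenation over the union of taxa (missing genes gap-filled, partition
map kept); a simplified conserved-block filter (keep maximal runs of
columns with gap fraction ≤ 0, majority-residue frequency ≥ 0.5, runs
≥ 10 columns — all three configurable) standing in for heavier
alignment-masking tools; p-distances under pairwise complete deletion;
neighbor joining by the canonical Q criterion with deterministic
lowest-index tie-breaking (negative branch-length estimates clamped to
zero); and a column-resampling bootstrap scoring each internal edge of
the point-estimate tree by the percentage of replicates containing its
bipartition. NJ is implemented in the package to pin down tie-breaking;
the test suite cross-checks it against scikit-bio's independent NJ and
against an exhaustive-topology least-squares oracle on random additive
matrices (4–8 taxa). `is_sister_pair` answers whether two taxa form a
cherry via the bipartition {A, B} | rest, which is independent of the
rooting outgroup.

## Problem sizes and numerical choices

Simulation-based checks run at sizes chosen to make sampling bounds
informative while keeping any laptop run fast: 15,706 bp for composition
recovery (±1 point on A+T), 10⁵ codons for RSCU recovery (±0.05),
10 kb / 6–7 taxa / 100 bootstrap replicates for topology support
(expecting ≥ 95% on strong-signal trees). Rounding happens only at render
time; every stochastic entry point takes an explicit seed and the
pipeline writes byte-identical bundles for identical (config, seed).

## Known limitations

* No de-novo annotation: ORFs, tRNA structures and anticodons are inputs.
* The event classifier is pairwise and greedy; complex multi-gene
  rearrangements legitimately come back as `unclassified`.
* The block filter is a simplified stand-in, not a reimplementation of
  any published masking algorithm.
* p-distance + NJ underestimates support structure on saturated or
  heterogeneous real data; use it for simulation studies and smoke
  checks, not publication trees.
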