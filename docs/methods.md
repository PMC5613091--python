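# Methods

This note documents the models, conventions and numerical choices behind
`plasmidfusion`, and what the synthetic-data generator does and does not
emulate.

## Problem setting

Alphaproteobacterial genomes are typically multipartite: a chromosome plus
extrachromosomal replicons (ECRs). Most ECRs replicate via RepABC modules —
operons of the partitioning genes *repA*/*repB* (ParA/ParB homologs) and the
replicase *repC*, with the origin of replication inside the *repC* coding
sequence and a regulatory antisense RNA between *repB* and *repC*. Downstream
of *repC* sits a doublet of 14-nt perfect inverted repeats, the cis-acting
anchor of the partitioning protein; the arm sequence distinguishes
compatibility groups (arm `TTAACAG` for group 1, `TTCACAG` for group 2 — a
single reciprocal exchange at the third arm position, hence positions 3 and
12 of the full motif). A composite (fusion) plasmid retains the replication
modules, nucleotide composition, codon usage and gene inventory of both
donors; the package's purpose is to read those imprints back out.

## Replication-module detection and palindrome typing

Detection is annotation-driven: features carry an explicit role
(`repA`/`repB`/`repC`) or match configurable product-string regexes. A module
requires all three roles on one strand in transcription order with each
intergenic gap ≤ `max_operon_gap` (default 2,000 bp; generous because of the
antisense-RNA spacer between *repB* and *repC*). Genes are consumed greedily
left-to-right, one module each. A *repC* with no partner within the gap bound
is reported as a solitary replicase.

Typing scans the window from 500 bp upstream of *repA* to 500 bp downstream
of *repC* (wrapping on circular molecules) for the configured 14-mers at
Hamming distance ≤ `max_mismatch` (default 0; 1 for sensitivity analyses).
Consecutive same-group hits whose spacer — intervening bases, exclusive —
lies in [11, 42] bp are paired greedily into doublets; the best doublet
(fewest total mismatches, then leftmost) labels the module, and a module with
no doublet is `untyped`. Scanning is single-stranded on the forward sequence:
both stated motifs are their own reverse complement, so hits are
strand-symmetric; this is asserted in the test suite rather than assumed.
Every configured motif must itself be a perfect inverted repeat (config
error otherwise).

## Composition analysis

* Windowed G+C content: (G+C)/(A+C+G+T) per window (default 1,000 bp, step =
  window/10), Ns excluded from numerator and denominator; a
  deviation-from-mean track accompanies it. Windowed skew: (G−C)/(G+C)
  (default 10,000 bp). Windows with empty denominators are missing (NaN).
* The cumulative skew accumulates +1 per G and −1 per C; its value after the
  final base equals #G − #C exactly.
* Landmark prediction uses the convention that the leading strand is G-rich:
  the cumulative minimum is the origin, the maximum the terminus (a swap flag
  inverts this). On circular molecules the *detrended* cumulative skew
  (C_i − i·C_L/L) is used, which makes the extremum positions exactly
  equivariant under rotation even when the total G−C is nonzero; raw
  cumulative skew is still what the profile type stores. Ties break to the
  smallest position with a warning; an extremum at the 0/L seam of a circular
  molecule is reported as position L.
* In-silico ligation excises an interval (wrap allowed) and re-circularizes
  it; contained features are re-coordinated, features straddling a cut are
  dropped with a warning. Running the skew machinery on the ligated molecule
  recovers the donor replicon's own ori and terminus.

## Codon usage and chromid classification

RSCU for codon *i* in a synonymous family *f* of size *n_f* is
`count_i / (Σ_f counts / n_f)`; the profile spans the 59 codons of bacterial
code 11 that belong to degenerate families (ATG/TGG excluded, stops
excluded). Counting skips N-containing codons and truncates out-of-frame
CDSs to the last full codon with a warning; alternative start codons are
counted as their literal codon, since RSCU measures usage, not initiation.
Non-empty family means equal 1 exactly.

Ordination is a centered, unscaled PCA (RSCU is already family-normalized; a
scale switch exists). Component signs are fixed by making each component's
largest-magnitude loading positive, so runs are deterministic. Explained
variances are reported over all components and sum to 100%. The dendrogram
uses average linkage on Euclidean RSCU distance (both configurable; the
analysis is robust to this choice at the separations involved) and exports
Newick text.

Chromids are ECRs whose codon usage matches their chromosome's. The
classifier formalizes this: a replicon is a chromid iff its Euclidean RSCU
distance to its own chromosome is ≤ `threshold_factor` (default 0.5) × the
median pairwise distance among the chromosomes of the genome set. The median
inter-chromosome distance is the natural scale: congeneric chromosomes
differ by drift far more than a co-evolved ECR differs from its own
chromosome, and using the factor rather than an absolute cut makes the rule
invariant to the overall spread of the set. A single-genome set has no such
scale and falls back to an absolute threshold (default 1.5, roughly midway
between sampling noise at the 100-kb replicon scale, ~0.4, and the distance
of a genuinely alien codon-usage regime, ~3.8) with a warning.

## Gene-origin painting and fusion breakpoints

Hit tables are inputs (the package never runs a homology search; results are
database-version dependent and explicitly not reproduced). Per gene:
self-genome hits (TaxID set, default {293088}) are dropped, hits with
E-value ≥ 1e-5 are dropped, survivors are ordered by ascending E-value with
deterministic tie-breaks (bitscore descending, then subject id) and capped
at 500; the top hit's order is the gene's origin, and the close-group share
(default order Rhizobiales, TaxID 356) of the kept hits gives a transparent
vertical/putative-HGT flag at a 0.5 threshold. This flag is a deliberately
simple surrogate for kernel-density HGT discovery tools, not a
reimplementation.

Block segmentation votes only with genes of focal origin (default
Rhizobiales/Rhodobacterales); genes with other/no origin and genes matching
the masked-product regex (default `transposase`) are neutral and never break
a block — transposases scatter by intragenomic transposition and would
otherwise shred the donor architecture. Voting labels are majority-smoothed
over a `min_block` (default 3) gene window; runs shorter than `min_block`
are discarded as noise; surviving same-origin runs merge; if nothing
survives, the replicon is one block of the globally dominant origin.
Breakpoints are midpoints of inter-block gaps, with first/last blocks merged
across the seam of circular molecules.

## The synthetic-data generator

The default composite-plasmid spec emulates the 259-kb fusion plasmid: a 200-kb
rhodobacteral backbone at G+C 0.62 carrying a roseobacter-type RepABC operon
with a group-2 palindrome doublet, fused to a 60-kb rhizobial insertion at
G+C 0.58 carrying its own RepABC operon (segment ori planted inside *repC*),
a group-1 doublet and a solitary replicase. Module-flanking primer sites are
planted so the two operon amplicons are exactly 4,415 and 4,986 bp. The
four-replicon genome-set preset adds a 240-kb chromosome and two chromids
(140/100 kb) with one rhizobial operon each: 4 modules + 1 solitary
replicase genome-wide.

Generator conventions (not claims about any particular genome):

* Gene lengths log-normal (median 900 bp, σ=0.35, clipped to 300–3,000 bp,
  multiples of 3); intergenic gaps geometric (mean 120 bp); strands random.
* Codon archetypes: per-family codon weights jittered by Gamma draws
  (concentration 8, giving ~0.5 RMS per-codon RSCU separation between two
  independent archetypes) and scaled by `exp(k · GC(codon))` with *k* solved
  by bisection so a sampled gene's expected G+C equals the segment target.
  Related (congeneric-chromosome) archetypes perturb a base archetype at
  concentration 20, placing congeneric chromosomes a few-fold above
  within-replicon sampling noise but well inside the alien separation —
  the geometry the chromid rule needs a scale from.
* Segment G+C is calibrated to ±0.005 of target by flipping intergenic
  bases, which leaves gene codon structure intact.
* Skew is injected by re-assigning each G/C base, with probability equal to
  the target amplitude, to G on the leading strand and C on the lagging
  strand (leading = ori→antipodal terminus within each segment). This leaves
  G+C content unchanged and produces a windowed skew amplitude equal to the
  swap rate; it slightly perturbs codon usage, which the archetype
  separation dwarfs.
* Hit tables: 5–50 hits per gene with log-uniform E-values in [1e-180,
  1e-3] so the 1e-5 cutoff is exercised on both sides; the best qualifying
  hit carries the gene's (possibly noised) origin label; occasional
  self-genome hits with excellent E-values test self-exclusion; a small
  `none_rate` (default 0.03) of genes receive only above-cutoff hits.
* Label noise: ordinary genes flip, at `noise_flip_rate` (default 0.10), to
  a uniformly random *wrong* order — best-hit misassignment scatters across
  the database's taxa rather than converging on the one opposing focal
  order. Transposase-annotated genes (4% of ordinary genes) instead flip to
  the opposing focal order half the time, emulating recent intragenomic
  transposition and giving the transposase mask something real to do.

All randomness flows from one seeded NumPy generator; emissions are
byte-identical across processes for a fixed seed, and every planted
coordinate is re-checked against the emitted sequence before return.

What the generator does **not** emulate: phylogenetic signal within hit
tables (orders are labels, not trees), amelioration gradients at segment
edges, repeat-driven rearrangements, assembly artifacts, and operon-level
transcriptional structure beyond gene placement. Passing recovery tests
therefore demonstrates correctness of the analysis machinery under the
stated statistical structure, not performance on real genomes with weaker or
confounded signals.

## Problem sizes

The acceptance script runs the full-size scenario (260-kb composite,
four-replicon genome set, three-genome chromid comparison). The test suite's
multi-seed property suites run scaled replicas — 60+20-kb fusions for
breakpoint recovery (50 seeds), 100-kb replicons for ori recovery (20 seeds,
skew amplitude 0.05), 60/40-kb replicons for chromid recovery (50 seeds) —
the same planted structure at sizes where a 50-seed sweep stays cheap.

## Known limitations

* Operons wrapping the sequence origin are not detected (the generator never
  plants them; real wrap-spanning operons would need rotation first).
* The close/distal flag is threshold-based; no attempt is made to model
  hit-score distributions.
* `segment_origin_blocks` reports at most one dominant origin per block; it
  does not model nested insertions.
* In-silico PCR is exact-match only — no melting-temperature or mismatch
  tolerance model.
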