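# Methods

## Scope and coordinate conventions

All public interfaces use 1-based inclusive coordinates (the GFF3 / tabular
alignment convention); any half-open arithmetic is internal. Sequences are
normalized to uppercase A/C/G/T/N: U maps to T and ambiguity codes other than
N map to N, and N bases are excluded from the denominators of GC/AT content.

## Non-redundant origin dataset

Origin catalogs rarely agree on boundaries, so merging is positional: the
primary set is kept verbatim and a supplementary record is added only if its
reciprocal overlap with every already-accepted record is below a threshold
(default 0.5) on the same chromosome. Reciprocal overlap is
`min(overlap/len(a), overlap/len(b))`, making the predicate symmetric and the
merge idempotent; supplements are processed in priority order, so ties
resolve deterministically toward the higher-priority source. Records supplied
as bare sequences are placed by a unique exact-match scan of both strands;
zero or multiple loci reject the record. The 0.5 threshold and the
priority-order rule are this package's explicit choices — catalog curation
practice varies and no single published rule exists to copy.

## Homology search and filtering

Two engines share one contract. The tabular adapter ingests standard
12-column alignment output and applies the three filters: identity ≥ 90%,
query coverage ≥ 90% (100·alignment length/query length, capped at 100), and
E ≤ 5e-10. The built-in engine indexes exact 12-mers of each query (both
strands) and, at every seed match, places the full query ungapped on the
subject diagonal, scoring identity by direct base comparison; placements
clipped at chromosome ends lose coverage accordingly. Because the engine is
ungapped it is exact for panels whose divergence is substitution-only (the
synthetic generator's regime) and approximate otherwise; its E-values are a
Karlin–Altschul-style estimate (λ = 1.33, K = 0.621 for +1/−2 ungapped DNA
scoring) used for ranking only — under this engine filtering is by identity
and coverage alone. Overlapping hits of one origin on one strain chromosome
are merged into a single presence event (interval union) before any counting.

Self-similarity within the reference: an origin is *unique* iff its only
passing hit reciprocally overlaps (≥ 0.5) its own annotated locus; every
other locus is reported as an intra- or inter-chromosomal pair.

## Conservation, pan/core curves, statistics

The presence matrix restricts hits to the strain chromosome corresponding to
the origin's reference chromosome (identity mapping by default, or a
per-strain alias table); for origins known to be multi-locus, their duplicate
chromosomes also count. *Conserved* means present in strictly more than 90%
of strains — with 104 strains the boundary is 94, with 50 strains 46. Core
origins are those present in every strain.

Pan (union) and core (intersection) accumulation curves are computed over
random strain orderings (default 1000 permutations, seeded; 200 in the
bundled pipeline runs for speed). Optional diagnostics fit Heaps' law
`κ·n^γ` to the median pan curve and `A·e^(−Bn) + C` to the median core curve;
these fits are descriptive conveniences, not the basis of any call.

The subtelomeric deficit uses a one-sided Mann–Whitney U (alternative:
subtelomeric homolog counts lower). Mann–Whitney p-values are exact (scipy's
exact null distribution) when both samples are ≤ 25 and tie-free, else the
midrank normal approximation with tie and continuity corrections. Timing
correlation is sample Pearson r between homolog count and replication timing
(Trep-style values, smaller = earlier; a flag flips orientation), with a
two-sided t-test p and a rank-sum comparison of timing between conservation
classes. Enrichment is one-sided Fisher's exact per term on the
`[[k, n−k], [K−k, N−n−K+k]]` table with Benjamini–Hochberg FDR; the
background is the analyzed annotation set, stated explicitly rather than an
implicit proteome default. PCA standardizes columns and fixes component signs
by making each component's largest-magnitude loading positive.

## Positional context

Gene strand is ignored; adjacency is purely positional. The gap convention is
the number of bases strictly between two intervals (`b.start − a.end − 1`).
An origin is *intersected* when it shares ≥ 1 bp with any gene, else
*intergenic*; gap ties break toward the smaller gene start with all tied
genes recorded. Subtelomeric means within 20 kb of either chromosome end
(positions ≤ 20000 or ≥ L − 20000 + 1). Conserved adjacent genes reuse the
strict >90% rule, counting a gene as adjacent when it is the left or right
neighbor of, or overlaps, the origin's homolog in that strain; strain gene
ids pass through an ortholog map (identity for synthetic panels) and unmapped
genes count as absent.

## ACS motif model

Probabilities are `(count + pseudocount) / (n + 4·pseudocount)` with
pseudocount 0.5; log-odds are `log2(probability / background)` in bits with a
uniform background by default (a genome-composition background is available).
The degenerate consensus covers, per column, all bases whose raw
(pre-pseudocount) frequency reaches 0.25. Scanning slides the log-odds matrix
over both strands and reports windows scoring at least 0.8 of the maximum
attainable score; windows containing N are skipped. The 0.8 threshold and
strand policy are package choices recorded in run metadata — counts of
"segments containing an ACS" depend on them and are not comparable across
different thresholds.

## Repeat finding

Maximal exact repeats in four modes — forward (substring occurs twice),
reverse (matches its reversal elsewhere), complement (matches the base-wise
complement), palindromic (matches the reverse complement) — at minimum length
8, reporting the 50 longest (ties by position). The search run-length encodes
each diagonal of the comparison between the sequence and its per-mode
transform, so every hit is maximal by construction; a locus matching its own
transform (a palindrome at one position) is not a repeat. Significance is by
length threshold only; no E-value model is attached, so repeat *statistics*
are descriptive. The O(n²) diagonal sweep targets origin-scale inputs (≤ a
few kb), not whole chromosomes.

## Synthetic panels

The generator emulates the structure the pipeline analyzes, with defaults
chosen once as a realistic desk-scale panel: 4 chromosomes × 200 kb at 38%
GC; 10 origins per chromosome (one per 20 kb slot, guaranteeing two
subtelomeric origins per chromosome), each 150–300 bp at 70% AT with one
planted word drawn uniformly from the `WTTTAYRTTTW` degeneracy; genes
(800–1500 bp) tiled in every inter-origin gap, with 30% of origins overlapped
by their right-flanking gene (overlap ≈ 40% of origin length); 2 internal
origins duplicated into subtelomeres of other chromosomes; 50 strains derived
by i.i.d. substitutions at 0.005/bp and per-locus origin deletion at 0.02
(internal) vs 0.5 (subtelomeric), deletions replaced in place by fresh
background so strain coordinates stay reference-aligned; timing
`t0 − b·(conservation fraction) + N(0, σ)` with t0 = 40, b = 20, σ = 2
(minutes-like, smaller = earlier); gene expression Normal(10, 2) for
intergenic-adjacent vs Normal(8, 2) for origin-overlapping genes; 20% of
genes marked essential; strains assigned uniformly to five niche labels. All
randomness flows from a single seed; identical seeds give byte-identical
output files.

The analytic expectation for presence is `(1 − p_del) · P(identity ≥ 90%)`
per locus, the identity term being the Binomial(L, substitution rate) tail
`P(X ≤ ⌊L/10⌋)`, combined across an origin's loci as one-minus-product of
per-locus absence. This neglects the (negligible at default rates)
possibility that every 12-mer seed is disrupted while identity stays ≥ 90%.

What synthetic panels do not show: real strain panels have indels,
rearrangements, aneuploidy, shared phylogeny (deletions are not independent
across strains) and annotation noise. Passing tests demonstrate the
correctness of the pipeline's arithmetic and calls under the stated
generative model, not field performance on downloaded assemblies.

### A note on calibration checks

With 50 strains and internal deletion probability 0.02, an origin's presence
count is Binomial(50, ≈0.98) — strongly skewed, so a normal ±3·SE band around
the expectation is unreliable for single origins (any origin with ≥ 4
deletions breaches it; exact per-origin probability ≈ 1.6%, so a 40-origin
panel breaches with ≈ 35% probability even when perfectly calibrated). The
suite therefore checks generator calibration with exact binomial acceptance
bands at a Bonferroni-corrected family level of 0.1%, which keeps power
against genuine miscalibration without flagging ordinary sampling extremes.

## Problem sizes

Bundled runs use the default panel (40 origins × 50 strains, 800 kb per
genome) with 100–200 pan/core permutations; unit oracles use exhaustive
enumeration up to 6 strains (pan/core), pooled sample sizes ≤ 10
(Mann–Whitney), 1000 random tables (Fisher), 1000 random layouts (interval
logic), 100 random sequences ≤ 2 kb (repeats). These sizes were chosen so the
whole suite completes in a couple of minutes while every check remains
exhaustive or statistically powered.
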