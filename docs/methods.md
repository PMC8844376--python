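# Methods

This note documents the models, rules and numerical choices behind the
package, and what the synthetic cohort does and does not establish.

## Variant model and normalization

Variant positions are 1-based (VCF convention); bins and annotation
intervals are 0-based half-open. Every alternate allele is normalized by
removing the shared allele suffix, then the shared prefix (always keeping
one anchor base), then left-shifting while the trailing bases allow —
i.e. the most parsimonious, leftmost representation. Biallelic records
that normalize to the same position are merged into one multi-allelic
site: the longest REF wins, shorter alleles are extended with the
uncovered reference suffix, and the merged alternate alleles are ordered
by (length, sequence) for determinism. A haplotype carrying two different
merged alleles at one locus cannot be represented and is set missing.
Missing or unphased-heterozygous genotypes become missing haplotypes and
are dropped from every frequency denominator; nothing is imputed (a
strict mode raises instead). SNP alternate alleles at an indel site are
retained in denominators but excluded from the marker's allele set.
Only autosomes (`chr1`–`chr22`, with or without the `chr` prefix) enter
the analysis.

## Random-sequence classification

An indel sequence S with reference flanks L and R (12 bp each; for
deletions, the flanks of the deleted span; for insertions, of the
insertion point) is an **expansion** iff some perfect tandem array — two
or more complete adjacent copies of a unit of length 1–15 bp — inside
`L + S + R` contains the whole S span. This single containment rule
reproduces the intended case split: a pure array S = u^k with k ≥ 2 is an
expansion unconditionally; a single-copy S counts only when the flanking
sequence completes an array across the junction, which covers both the
aligned case (L ends with S, or R starts with S) and the straddle case
(a rotation split across both flanks). A lone base whose insertion
completes a longer-unit array (G between `..TA` and `CGCC..` completing
`GCGC`) is likewise an expansion — mechanistically a slippage product.
The verdict is labelled monomeric when S is a single repeated base,
multimeric otherwise. Implementation detail: for each unit length q the
maximal q-periodic run covering S is found via the q-shift match profile
`T[i] == T[i+q]` (O(|T|) per q); an independent brute-force scan over all
(unit, offset) pairs backs it in the tests.

Flank randomness is separate: a flank fails when it contains a
homopolymer run > 5 bp or a perfect 2–15 bp array with ≥ 2 copies
totalling ≥ 8 bp. These two thresholds are package defaults (exposed in
`ClassParams`): no published cutoffs exist for "random" 12-mers, and the
chosen values are strict enough to reject slippage-prone context while
loose enough that typical uniform random 12-mers pass (the spectrum of
flanks accepted/rejected is pinned down by a brute-force scan the tests
compare against). Classification is always performed on the reference
context, not the alternate haplotype.

## Marker criteria

An allele is *valid* when its haplotype-count frequency in the whole
cohort is strictly greater than 0.01 (the strictness of the comparison is
configurable). A **multi-allelic InDel** needs ≥ 2 indel alternate
alleles, all indel alleles and flanks random, and ≥ 3 valid alleles
counting the reference — so a tri-allelic marker corresponds to exactly
one secondary mutation on top of an existing bi-allelic indel. A
**multi-InDel** is a chain of random-context indel loci in which every
consecutive gap is ≤ 20 bp (gap = reference bases strictly between the
upstream REF span and the downstream start; insertions occupy only their
anchor base). A strict *span* mode additionally bounds the first-to-last
distance and splits greedily left-to-right into maximal clusters; the
default chaining mode matches how the threshold was derived from
adjacent-pair distances. Multi-InDel alleles are the phased haplotype
vectors over the member loci; the same > 0.01 / ≥ 3 rule applies to them.
Multi-allelic member sites are allowed inside multi-InDels.

The mean-difference statistic MDV(s) quantifies the local drop of the
adjacent-distance histogram. Its contiguity scan for the suggested gap
threshold starts at s = 3, the smallest distance whose left averaging
window stays within the domain of possible distances (for s < 3 the
window reaches distances < 1 bp, whose counts are identically zero,
making the statistic meaninglessly negative).

## Genome scan, annotation, populations

Densities are counted into 100-kb half-open bins by the marker's
normalized start (multi-InDels: first member). GC content excludes N
bases from the denominator; the mean recombination rate is the
map-overlap-length-weighted mean, with unmapped bases carrying no weight;
bins with undefined values are excluded pairwise per factor from the
Pearson correlations (scipy's t-transform p-values). The empty-bin
fraction can be computed over all bins or over non-N bins (configurable;
default all). Markers are annotated by point containment of their anchor
(any-overlap of the span available behind a flag): repeat class of the
longest-overlap containing repeat, and gene context with priority
CDS > non-coding exon > intron > intergenic, where "non-coding exon"
means exonic but outside every CDS. Population presence uses the same
> 0.01 / ≥ 3 rule within each superpopulation; allele ranks stay fixed by
global nomination when reporting per-population means; an allele valid in
exactly one population is that population's specific allele. For the
share of markers with population-specific alleles both denominators (all
markers, and five-population-shared markers) are emitted, since either
reading is defensible.

## Synthetic cohort

The generator emulates the study conditions at desk scale: five
superpopulations of 40 diploids each (400 haplotypes), two 5-Mb autosomes
with alternating 1-Mb GC blocks (0.35/0.55), one N-masked block, a small
chrX with records that must be excluded, a piecewise-constant genetic map
(log-normal rates, 500-kb segments, deliberately not covering the last
500 kb of chr2), and non-overlapping repeat/gene annotations with
CDS ⊂ exon ⊂ gene nesting. About 2,000 variants are planted GC-weighted
(denser in high-GC blocks) with ≥ 60 bp separation outside deliberate
clusters, so no unintended adjacency below the 20-bp bound can arise:
background SNPs and bi-allelic random indels; repeat-expansion indels
(written as genuine u^k arrays into the reference) and flank-repeat
contexts that the filter must reject; qualifying multi-allelic sites
(3–4 alleles, valid targets ≥ 0.04); low-frequency third alleles
(target 0.004, i.e. ≈ 1.6 of 400 haplotypes); mixed SNP/indel sites;
population-specific third alleles; and adjacent clusters sampled from
joint haplotype tables — by default three of the four two-locus
combinations, the secondary-mutation model, with dedicated four-combination
(recombination/typing-error escape path), fully-linked (two-allele), and
wide-gap negative controls. Haplotypes are sampled at the haplotype level
(multinomial per locus, or per joint table for clusters) and paired into
diploids within population; per-population targets get mild Dirichlet
differentiation with an AFR minor-allele boost and an EAS damping, so the
qualitative population pattern (AFR highest third-allele frequencies) is
reproducible. Half of the multi-allelic sites are emitted as split
biallelic VCF records to exercise merge-on-read.

The manifest records every planted variant with its class, targets and
realized (sampled) frequencies, and derives each expected verdict
*arithmetically from the realized counts* with the same thresholds — so a
low-frequency allele that drifts above 0.01 flips its expected verdict
rather than breaking the truth comparison, and exact recovery is
checkable at any seed. Escape-path (four-allele) clusters are deliberately
over-represented relative to real cohorts to keep that branch exercised;
shares of tri-allelic markers in the synthetic cohort are therefore lower
than in a sequencing cohort. What the passing end-to-end test shows is
that the implementation applies the stated criteria exactly; it does not
show robustness to phasing or genotyping error, LD structure, or repeat
families with imperfect arrays — none of which the generator models.

## Problem sizes and defaults

The analysis scripts and the acceptance run use the desk preset
(2 × 5 Mb, ~2,000 variants, 200 diploids), which finishes in seconds; the
classifier/oracle cross-check uses 10,000 random triples and the MDV
exactness check 1,000 random histograms. The 20-bp threshold
demonstration uses a constructed genome-scale decay histogram
(N_s = 505·0.93^s + 50) because desk-scale pair counts per distance are
single digits, far below the > 25 MDV cutoff. All thresholds
(`af_min = 0.01`, `min_valid_alleles = 3`, `max_gap = 20`,
`flank_len = 12`, unit range 1–15, MDV cutoff 25, bin width 100,000)
live in `PipelineConfig`, round-trip through YAML, and the effective
configuration is written next to every output set.

## Known limitations

- Perfect-array detection only: degenerate/imperfect repeats are treated
  as random context.
- Transposon insertions are not recognized by homology; a mobile-element
  insertion with non-repetitive sequence would pass the random filter.
- The reader's record-merging window assumes left shifts below 1 kb,
  adequate for short indels but not for structural variants (which are
  out of scope, as are liftOver, CRAM/BAM and sex chromosomes).
- Pearson correlations on count data are reported as-is, matching the
  analysis design; no variance-stabilizing transform is applied.
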