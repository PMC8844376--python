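# mmindel

Discovery and characterization of **multi-allelic InDels** and
**multi-InDels** (jointly *MM-InDels*) carrying random — i.e. non-repeat —
insertion/deletion sequences, from phased population genotype data.

Most insertion/deletion polymorphisms are bi-allelic, and a large share of
them are expansions or contractions of tandem-repeat arrays generated by
polymerase slippage. An indel whose sequence is *random* (not an expansion
of a monomeric base or of a 2–15 bp repeat unit, in a non-repetitive 12-bp
flank context) instead marks a unique mutational event. When a **second**
insertion/deletion hits the same locus, the locus becomes multi-allelic
(three or more alleles); when it hits within a few base pairs, the phased
haplotypes over the neighbouring loci form a composite **multi-InDel**
marker. Both marker classes are informative for population comparison and
forensic resolution, and their tri-allelic excess is a direct signature of
sequential (secondary) mutation.

The package is aimed at population/forensic geneticists who have a phased
cohort VCF, a sample→superpopulation panel (AFR/AMR/EUR/EAS/SAS), a
reference FASTA, and optionally a HapMap-style genetic map and repeat/gene
annotations.

## The procedure

A site stream is normalized (left-aligned, parsimony-trimmed; split
biallelic records at one locus are merged) and filtered by:

1. autosomal location;
2. every indel allele is a **random sequence** — no perfect tandem array of
   a unit *u* (1 ≤ |*u*| ≤ 15) with ≥ 2 full copies inside
   `flank + allele + flank` contains the allele;
3. the 12-bp flanks are random (no homopolymer run > 5 bp, no 2–15 bp
   array ≥ 8 bp with ≥ 2 copies);
4. allele frequency > 0.01 in the whole cohort counts an allele as *valid*
   (haplotype-count frequencies; missing haplotypes dropped from
   denominators);
5. ≥ 3 valid alleles per marker;
6. multi-InDel members lie within a ≤ 20 bp gap of each other.

The 20-bp gap bound is motivated by the adjacent-InDel distance histogram
N<sub>s</sub> through the *mean difference value*

MDV(s) = (N<sub>s−2</sub> + N<sub>s−1</sub>)/2 − (N<sub>s+1</sub> + N<sub>s+2</sub>)/2,

the local drop of pair counts at distance *s*: the suggested threshold is
the largest *s* with MDV > 25 contiguously. Multi-InDel alleles are the
phased haplotypes over the member loci ("0-0", "1-0", …). Markers are then
ranked (alleles 1..6 by descending global frequency), binned into 100-kb
windows together with SNP/InDel densities, GC content and mean
recombination rate (Pearson correlations), annotated against
SINE/LINE/LTR repeats and gene models, and compared across the five
superpopulations (presence, entire-allele vs. loss/birth,
population-specific alleles, Venn cells).

A fully synthetic data generator (`mmindel.synth`) emits all the input
formats with a machine-readable truth manifest, so the whole pipeline is
testable without downloads.

## Worked example

```bash
mmindel simulate --outdir results/sim --seed 7
mmindel all --vcf results/sim/cohort.vcf --panel results/sim/panel.tsv \
    --reference results/sim/reference.fa \
    --genetic-map results/sim/genetic_map.txt \
    --repeats-bed results/sim/repeats.bed \
    --genes-gff results/sim/genes.gff3 --outdir results/pipeline
```

or, as the scripted analysis sequence:

```bash
python analysis/01_simulate.py            # synthetic cohort + truth
python analysis/02_discover_markers.py    # criteria funnel + truth check
python analysis/03_adjacency_threshold.py # distance histogram, MDV rule
python analysis/04_genome_scan.py         # 100-kb densities, correlations
python analysis/05_annotation_context.py  # repeats and gene context
python analysis/06_population_comparison.py
```

`02_discover_markers.py` prints (seed 7):

```
1954 sites parsed (777 random-context indels)
multi-allelic filter funnel:
  input                  1954
  not_autosome           0
  lt2_indel_alts         1787
  not_random             40
  lt_min_valid_alleles   29
  kept                   98
-> 98 multi-allelic markers, 88 multi-InDels
truth check: multi-allelic FP=0 FN=0; multi-InDel FP=0 FN=0
```

Reading: of 1,954 parsed sites, 1,787 lack two indel alternate alleles
(ordinary SNPs/bi-allelic indels), 40 fail the random-sequence or flank
test (planted repeat expansions and flank arrays), 29 lack a third valid
allele, and the 98 survivors are exactly the planted qualifying loci —
zero false positives or negatives, and likewise for the 88 multi-InDels.
`04_genome_scan.py` then reports a positive marker-density correlation
with GC content (the generator plants variants GC-weighted), and
`06_population_comparison.py` shows the AFR cohort with the highest mean
frequency of third-and-rarer alleles, mirroring the planted
minor-allele skew.

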