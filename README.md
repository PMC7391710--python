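# ldfingerprint

Sample-swap detection for NGS datasets via genotype-likelihood
fingerprints over linkage-disequilibrium (LD) blocks.

Two sequencing datasets from the same donor share genotypes; datasets from
different donors do not. `ldfingerprint` compares datasets through a
*haplotype map* — a genome-wide set of LD blocks, each an anchor SNP plus
tightly linked member SNPs (member r² ≥ 0.85 with the anchor, anchor-pair
r² ≤ 0.10). Reads overlapping *any* SNP of a block are translated to the
anchor's alleles via the stored phase, folded into per-block diploid
genotype likelihoods (a *fingerprint*), and two fingerprints are compared
with a capped base-10 log-odds (LOD) score: positive favours a shared
donor, negative a swap, with |LOD| < 5 inconclusive. Because linked,
non-overlapping reads still inform the same block, the method works even
when two assays cover disjoint genomic footprints.

The package provides:

- **haplotype_map** — domain model, tab-delimited file dialect, validation
  and subsetting of LD-block maps.
- **map_builder** — map construction from a phased panel: MAF and
  cross-population stability filters, windowed LD pruning to independent
  anchors, LD-score-ordered greedy block building; plus the per-locus
  expected-information utility (maximal, 1.5·log₁₀2 ≈ 0.45, at MAF 0.5).
- **fingerprinting** — read/base filtering (non-secondary, non-duplicate,
  MQ > 20, BQ ≥ 20, one observation per read-pair), anchor-allele
  translation, log10 genotype likelihoods, fingerprint VCF persistence.
- **lod_scoring** — per-block likelihood-ratio terms with Hardy-Weinberg
  priors, a per-block floor (σ = −3) so no single locus dominates, prior
  odds applied as a constant shift, and MATCH/MISMATCH/INCONCLUSIVE
  classification at ±5.
- **screening** — database-scale screening: self-LOD-ranked representative
  triplets with single-swap repair, per-dataset flagging, true-donor
  nomination, cross-donor duplicate clustering, and a contamination
  mixture harness.
- **simdata** — seeded generators for phased panels with block LD
  structure, diploid individuals (including relatives and duplicate
  donors), SAM read sets with controllable assay footprints, and
  planted-truth screening cohorts. All tests run offline on these.

## CLI

All commands are under a single entry point, `ldfp`:

```sh
# compare two datasets (SAM/BAM or fingerprint VCF)
ldfp crosscheck --map map.tsv --left a.bam --right b.vcf \
    --output report.tsv [--prior-odds 1.0] [--cap -3] [--threshold 5] [--per-block]

# extract a reusable fingerprint VCF from aligned reads
ldfp extract --map map.tsv --input in.bam --sample NAME --output fp.vcf \
    [--min-mq 20] [--min-bq 20]

# build a haplotype map from a phased panel VCF
ldfp build-map --panel panel.vcf --output map.tsv \
    [--populations samples.tsv] [--genetic-map gmap.txt]

# screen a database of fingerprints for swaps
ldfp screen --map map.tsv --manifest manifest.tsv \
    --fingerprint-dir fps/ --output screen.tsv

# synthetic data
ldfp simulate panel  --seed 1 --output panel.vcf --map-output truth.tsv
ldfp simulate reads  --seed 1 --map map.tsv --output reads.sam
ldfp simulate cohort --seed 1 --n-donors 20 --datasets-per-donor 10 \
    --swaps 5 --out-dir cohort/

# LOD vs contamination fraction
ldfp contam --map map.tsv --ref-reads a.sam --contaminant-reads b.sam \
    --reference-fp ref.vcf --steps 10 --total-reads 5000 --seed 1 --output contam.tsv
```

Exit codes: 0 success, 2 usage error, 3 input/contract error.

### File formats

- *Haplotype map*: UTF-8 tab-delimited, `#` comments, header
  `CHROM POS NAME MAJOR MINOR MAF ANCHOR PHASE`; anchors reference
  themselves and precede their members; `PHASE` is `+` when a member's
  major allele rides with the anchor's major allele, `-` otherwise.
- *Fingerprint*: VCF 4.2, one record per anchor with `GT` (argmax
  genotype) and `GL` (log10 likelihoods, order AA,AB,BB), `INFO/NOBS`
  observation counts, and a header line binding the file to its map
  checksum.
- *Manifest*: TSV with columns `DATASET_ID DONOR PATH`.

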