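# Methods

## Scope and data model

`poolscan` analyses jointly-called pooled-sequencing variants downstream of
variant calling: the inputs are a multi-pool VCF (per-pool genotypes at pool
ploidy, per-allele read depths AD, genotype qualities GQ, and the site
metrics QUAL, QD, MQ, FS, HaplotypeScore, MQRankSum, ReadPosRankSum), a
known-variant catalogue, a VEP-style consequence table, a genome layout
(FASTA-index dialect) and gene intervals (BED or GFF3). Read-level
processing, variant calling and annotation are upstream of this package.

All internal coordinates are 0-based half-open; 1-based VCF coordinates are
converted exactly once, at read/write. Contigs absent from the genome layout
are skipped with a warning, keeping scans confined to the declared
chromosomes (typically the 29 cattle autosomes; the UMD3.1 autosome table
ships with the package).

## Hard filtering

A site fails when any *present* metric violates its strict GATK-convention
inequality (QUAL < 30, QD < 2, MQ < 40, FS > 60, HaplotypeScore > 13,
MQRankSum < −12.5, ReadPosRankSum < −8); values equal to a threshold pass.
Absent metrics never fail a site: GATK omits, for instance, rank-sum
annotations at sites without heterozygous calls, and treating absence as 0
would discard valid sites. Verdicts list every violated criterion, which the
tests exploit (relaxing exactly one criterion must remove exactly that
reason). Pools with GQ below 20 have their genotype masked; read depths are
kept, because the reads exist irrespective of genotype confidence and the
sweep scan works on reads. A record is dropped only when no pool retains a
genotype.

Within-pool zygosity has three classes — fixed (all alleles one non-reference
allele), segregating (≥ 2 distinct alleles), reference (all reference) — the
third being necessary because joint-called multi-pool VCFs contain pool-level
non-variant sites. Ti/Tv is computed over biallelic-expanded substitutions
(one per alt), which makes multiallelic handling deterministic; zero
transversions yields NaN with a warning.

## Novelty

Variants are keyed as (chrom, pos, ref, alt) after parsimony trimming:
shared trailing bases first, then shared leading bases with a position
shift (the bcftools/vt convention), always retaining one base per allele.
Full left-alignment through repeat runs needs the reference sequence and is
deliberately out of scope; the same trimming is applied to both query and
catalogue, so matching is representation-stable. The default match mode is
allele-exact (the dbSNP convention); a position-only mode exists behind a
flag. Reported proportions are rounded half-up to two decimals, and the
headline figure is the unweighted mean of per-pool proportions.

## Functional classes

Modern Sequence Ontology terms map onto the legacy class vocabulary
(Nonsynonymous_coding, Essential_splice_site, ...) used in per-breed summary
tables; unknown terms land in an `unmapped` bucket and are logged once. A
variant with annotations on several transcripts is reduced to its most
severe class under a fixed order (Stop_gain > Stop_lost >
Essential_splice_site > Nonsynonymous_coding > Synonymous_coding >
Splice_site > UTRs > miRNA > Intronic > Within_non_coding_gene >
Up/Downstream > Intergenic), chosen for determinism since no reduction rule
is standard; an `all` mode counts every annotation instead. With the
most-severe reduction, per-class counts partition each pool's classified
variants, and within-pool percentages sum to 100%.

## Density scan

1 Mb non-overlapping windows tile each chromosome; the trailing window is
truncated and densities always use the true window length in kb, so
telomeric windows are neither discarded nor inflated. Four categories are
counted per pool — all SNPs, missense, LoF (stop-gain ∪ stop-loss), novel —
and categories are not exclusive. The top fraction (default 1%) is selected
per category by density, ties broken by genomic coordinate; the cutoff
denominator counts all windows by default (simplest fixed denominator) with
a nonzero-only option. Genes overlapping a selected window by ≥ 1 bp are
ascribed to it, deduplicated and sorted.

## Sweep scan

Per pool and SNP, (n_MAJ, n_MIN) are the two largest per-allele read depths
(ties are harmless: Hp is symmetric in the two sums). Indels, mixed sites
and hard-filter failures never enter the scan. Windows are 150 kb sliding by
75 kb, **full windows only** — no truncated trailing window — so every
interior base is covered exactly twice. Windows with fewer than `min_snps`
SNPs (default 10; configurable, including 0) are unscored and excluded from
μ/σ and calling: near-empty windows make Hp degenerate. The Z-transform is
genome-wide per pool with the population standard deviation (divisor N),
consistent with treating the genome's windows as the full population — the
two-window case then gives ZHp = ∓1 exactly. Per-chromosome normalisation is
not used because empirical score distributions are reported genome-wide per
pool. Zero variance raises an error rather than returning NaNs.

Windows at or below each tier threshold (−4 candidate, −5 putative, −6
extreme) are merged when overlapping or book-ended on one chromosome into
*distinct loci*; tiers are called independently, so an extreme locus always
lies inside a candidate locus. Note that the number of merged loci is not
monotone in the threshold (selecting fewer windows can split a run into two
loci); what is monotone, and what the tests assert, is the selected-window
count and locus containment across tiers.

Applying the full-window convention to the 29 UMD3.1 autosomes yields
33,453 windows. Published genome-wide tallies for this assembly may differ
by a few tens of windows depending on edge handling and index provenance;
no natural convention (truncated tails, rounding, any-start) changes the
count by more than ~60 of 33 000, and none of the alternatives is better
motivated than full-windows-only, which keeps every window the same length
and every interior base covered exactly twice.

## Synthetic data generator

The generator emulates a three-breed pooled design: `n_pools = 3` pools of
`pool_size = 30` diploids (ploidy 60), `mean_coverage = 20` reads per pool
per site, one SNP per 250 bp on average, 11% indels, a known-catalogue
inclusion probability of 0.93, and a transition:transversion odds giving
Ti/Tv ≈ 2.2 — the study conditions the analyses target. Specifics:

- **Positions** are a Poisson process at `snp_rate`, with the rate multiplied
  inside planted hotspots; duplicate positions are dropped.
- **Allele counts** per pool are drawn independently from a neutral spectrum
  P(k) ∝ 1/k over k = 1..ploidy−1 derived-allele copies — the minimal model
  under which ZHp tails are meaningful. No linkage disequilibrium, shared
  drift or coalescent structure is modelled, and the pools are exchangeable;
  passing tests therefore demonstrate statistical behaviour of the methods,
  not realism of any particular breed's allele-frequency distribution.
- **Sweeps** multiply the minor-allele frequency by (1 − het_reduction)
  inside an interval (rounded to whole allele copies), for all pools or a
  configurable subset. Variant density is untouched, so the read-balance
  statistic, not SNP count, is the detecting signal.
- **Reads**: depth ~ Poisson(mean_coverage) per pool per site, split
  binomially by the pool allele frequency. No sequencing-error model.
- **Site metrics** are drawn from distributions clipped strictly inside the
  pass region, so that `inject_filter_failures` (or the
  `filter_fail_fraction` parameter) controls the failing set exactly —
  exactly round(fraction·N) records fail, and the filter stage must remove
  exactly those. The default failing fraction is 0, making failures an
  explicit, configurable perturbation rather than a background rate.
- **Consequences** are drawn per variant from term frequencies echoing a
  whole-genome annotation (≈62% intergenic, ≈27% intronic, ≈0.3% missense,
  rare stop events); ~5% of genic variants get a second, milder transcript
  annotation to exercise the severity reduction. Genes are a deterministic
  lattice (30 kb gene every 120 kb). Indels are generated so summary tables
  have content but never enter the sweep scan.
- All randomness flows through a single numpy Generator seeded once; a fixed
  seed reproduces every output file byte for byte.

## Validation experiments and problem sizes

The planted-sweep recovery study (in `poolscan.experiments`) uses a
3 × 30 Mb genome with five 300 kb sweeps at 95% heterozygosity reduction
under default pool settings, 20 replicate seeds in the test suite (10 in the
acceptance script): ≈ 360,000 variants and ≈ 1,200 windows per replicate,
sized so the whole study runs in about a minute while the sweep windows stay
a small fraction (~2%) of all windows, as in a genome-scale scan. Expected
behaviour, which the tests assert: ≥ 90% of planted sweeps overlapped by a
candidate locus (ZHp ≤ −4) and ≤ 1 false locus per genome. In practice
recovery is 100% with ZHp ≈ −8 at the planted intervals and no false calls.

The density hotspot check plants a ×5 hotspot over 2 Mb in a 104 Mb genome
(104 windows, so the top 1% holds exactly the 2 hotspot windows) and asserts
recovery across 20 seeds. The Hp implementation is checked against exact
rational-arithmetic recomputation from flat per-SNP lists over 1,000 random
windows, plus a brute-force per-window oracle over a small random genome.

## Numerical and degenerate-input choices

- Hp on a window with zero total reads is NaN (unscored), never 0.
- Z-transform requires ≥ 2 scored windows and non-zero variance; otherwise
  it raises.
- Proportions for empty pools are reported missing (NaN), not 0.
- Reported proportions use decimal round-half-up (2 decimals), matching
  common summary-table formatting.
- htslib stores INFO floats in single precision; VCF round-trips are exact
  at float32 resolution.
- `top_percent` and sweep calling are independent of input row order (stable
  sorts, coordinate tie-breaks).

## Known limitations

- Novelty matching cannot left-align indels through repeat runs without a
  reference sequence; identical variants spelled at different repeat offsets
  would not match.
- The generator's independent-pool, no-LD neutral model understates the
  variance of window statistics relative to real populations; thresholds
  validated here should be re-examined on real data.
- Per-pool scans assume the VCF's AD field is reliable at pool ploidy;
  depth-capped callers may bias Hp downward.
- The pipeline computes per-pool figures; cross-pool union totals are only
  meaningful when a merged multi-pool VCF is supplied.
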