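# Methods

This note documents the models behind each stage of the pipeline, the
parameter defaults and why they were chosen, the numerical conventions, and
what the synthetic-data generator does and does not emulate.

## Data model and conventions

Genotypes are unphased alternate-allele dosages in {0, 1, 2} with a missing
sentinel; only biallelic SNPs are represented (multi-allelic rows are
dropped at ingestion, not decomposed). VCF positions are 1-based;
interval files follow the half-open 0-based BED convention; conversion
happens only at the I/O boundary. All population-genetic statistics run on
**un-imputed** matrices, handling missing calls per site or per pair. The
declared imputation (`impute_missing`, per-SNP modal genotype, ties toward
the lower dosage) exists for structure/scan use only; haplotype-aware
imputation is out of scope.

The variant filter retains SNPs called in ≥ 50% of the individuals of
*every* population, ≥ 90% of all individuals, and with minor allele count
≥ 3. The per-population rule is evaluated literally on the metadata
`population` column, including very small populations; merging populations
is expressed by editing that column upstream, not by special-casing.

## Windowed statistics

* **Nucleotide diversity**: per site, π = 2p(1−p)·n/(n−1) over called
  alleles (identically the mismatching fraction among allele pairs).
  Sites called in fewer than two samples are skipped and counted.
* **Tajima's D**: non-overlapping half-open 5-kb bins on a 0-based grid per
  chromosome. Per bin, S counts segregating sites, k̂ sums per-site mean
  pairwise differences, and the sample size entering Tajima's constants is
  the **modal per-site called-allele count** in the bin — a declared choice
  for missing data; with low missingness it coincides with the
  complete-data formula. Bins with S = 0 are emitted as undefined.
* **Genotype LD**: r² is the squared Pearson correlation of dosage vectors
  over pairwise-complete samples, with same-chromosome pairs restricted to
  distances in [500 bp, 100 kb] (the lower bound suppresses within-tag
  comparisons in reduced-representation data; the upper bound caps the
  standard scan). The linkage-network stage deliberately lifts the cap.
* **Weir–Cockerham F<sub>ST</sub>** (two groups): per-SNP variance
  components a (among), b (between individuals within), c (within
  individuals) from group allele frequencies, sample sizes and observed
  heterozygosities; θ = a/(a+b+c), negative estimates retained. Windowed
  values use the ratio-of-sums Σa/Σ(a+b+c) over 5-kb windows stepped by
  1 kb; windows without usable SNPs are omitted.
* **Moving averages** are simple (unweighted) trailing means over the
  preceding *span* records within a chromosome; the first span−1 records
  are undefined. The `popstats` default span of 100 windows suits
  genome-scale visualisation; the locus-scale Δ profiles below use span 20
  (~200 kb of occupied bins at the simulated marker density), which is
  what allows extrema to be localised within ±1 Mb.

## Association scan

The scan tests whether each SNP's dosage tracks the focal resistance
genotype beyond genome-wide structure. Structure is summarised by K latent
factors taken as the leading principal components of the mean-centred
(mean-filled for estimation) dosage matrix; K is a user input (presets 18
and 4 reflect typical global panels of the two *Aedes* species), and a
variance-explained profile is emitted to guide the choice. Each SNP is
regressed by least squares on (intercept, focal dosage, factors); the
focal-coefficient t-statistic is the z-score. A deterministic least-squares
fit replaces an MCMC latent-factor sampler: the test target
(structure-adjusted association) is identical, and determinism removes the
need to combine z-scores across repetitions. Residual confounding is
absorbed by genomic-control recalibration, z ← z/√λ with
λ = median(z²)/0.4549 (the χ²₁ median); λ > 1 on unadjusted structured data
is itself a reported diagnostic. Two-sided normal p-values are BH-adjusted;
outliers fall below 1/(number of SNPs). Samples with unknown focal genotype
are dropped; SNPs with MAF < 0.05 are flagged untested. Factors collinear
with the focal contrast (|r| > 0.999) are dropped with a warning rather
than silently absorbing the signal.

## Background identification

Two complementary identifications of sweep backgrounds from outlier SNPs:

* **PCA + k-means** of focal-mutation homozygotes on the outlier-SNP
  dosage submatrix: seeded k-means (50 restarts) on the first two
  components replaces visual cluster assignment, with individuals beyond a
  configurable within-cluster distance quantile flagged *uncertain*
  (these are the individuals spread toward the PCA centre by missing data
  or recombination). A manual assignment table can override.
* **Haplotype screen**: individuals homozygous and non-missing at every
  screen SNP share a haplotype string → strict members. Individuals with
  at most one heterozygous-or-missing screen site attach to the unique
  strict haplotype consistent with their remaining sites; ambiguity leaves
  them unassigned rather than guessed.

The end-to-end experiment (`pipeline.sweep_recovery_experiment`) uses as
screen set the **32 strongest near-locus outliers** (smallest adjusted p
within 1 Mb of the locus). The cap matters: each carrier chromosome also
carries private singleton variants, so a screen over every near-locus
outlier (~150 SNPs at the simulated density) would disqualify carriers
from the one-deviation relaxation by construction; 32 SNPs matches the
scale of real multilocus screens and keeps the expected number of
singleton hits per carrier well below one.

## Δ contrasts and between-background differentiation

For one background versus its wild-type cohort, ΔX(window) =
X_background − X_wildtype for binned D and π; ΔLD is the difference of
moving-averaged binned r² profiles (pairs assigned to the bin of their
midpoint). Windows undefined in either cohort are undefined in Δ; swapping
cohorts negates every defined value exactly. The wild-type cohort is
configurable — all wild types, or wild types from the same populations as
the background — and recorded in output metadata. Between-background
differentiation uses the windowed Weir–Cockerham statistic with per-SNP
values above 0.25 highlighted.

## Linkage networks

Candidate SNPs at least 50 Mb from the sweep locus (distance measured from
the nearest interval edge) or on any other chromosome are scored once per
r² > 0.6 interaction with a SNP within 1 Mb of the locus; scores accumulate
into half-open 500-kb bins whose total equals the number of qualifying
pairs (conservation). The r² cutoff default of 0.6 is exposed as a flag; a
`--top-contigs` option restricts fragmented assemblies to the contigs with
the most interactions (ties broken by contig name). Gene annotation is
half-open interval overlap, so a gene straddling a bin boundary annotates
both bins.

## Copy number from depth ratios

Per sample: sites with depth < 1X are excluded (per sample, so site sets
differ between samples); the ratio is mean depth over coding-region sites
divided by mean depth over the two 10-Mb windows abutting the coding span
(interior excluded, flank sites pooled — i.e. site-count weighted; an
equal-window-weight flag exists because the choice is not forced). Samples
with fewer than 500 retained coding sites are excluded. The per-sample
sequencing effort cancels in the ratio, so a diploid region centres at 1
and a region at copy number c centres at c/2. Upstream/downstream
consistency is reported as the squared Pearson correlation of the two
flank means across samples. Group differences use a one-way fixed-effects
ANOVA; with zero within-group variance and distinct means the F statistic
is reported as infinite with p = 0.

## Admixture

f3(C; A, B) per SNP is (c−a)(c−b) − c(1−c)/(n_C−1), with sample allele
frequencies and the bias correction for estimating c from n_C alleles;
the statistic is the mean over informative SNPs, with a delete-one block
jackknife over consecutive 500-SNP blocks for the standard error
(block size is a flag; fewer than 20 blocks triggers an underpowered-data
warning). Significance is one-sided for f3 < 0, Bonferroni-adjusted over
the triads tested in a run. Note that a *degenerate* triad (target reused
as both sources) reduces to minus the bias correction and is therefore
strongly negative by construction — it is not a valid null; the
meaningful null is an unadmixed target, for which f3 > 0 (drift on the
target's own branch).

Admixture proportions: PC1 of the centred, frequency-standardised dosages
of the pooled source samples (SNPs polymorphic in the pool only), with
query samples projected using the same centring and loadings, missing
entries contributing zero deviation. α̂ = (x̄_B − x)/(x̄_B − x̄_A) clipped to
[0, 1]; the axis is oriented with source A negative so α̂ is the source-A
ancestry fraction.

## Synthetic-data generator

Forward construction, not coalescent simulation — the point is exact
ground truth for screening and contrast stages:

* **Structure**: Balding–Nichols. Ancestral frequencies Uniform(0.05,
  0.95); population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F); genotypes
  Binomial(2, p_pop). Default two populations of 50 diploids, F = 0.1,
  5,000 SNPs on two 20-Mb chromosomes, 2.5% missing calls — the scale of a
  reduced-representation population panel with the low missingness typical
  after filtering.
* **Sweeps**: carrier chromosomes are overwritten by a per-background
  haplotype (one fixed random allele per SNP, a function of the background
  label) over a tract [locus − max(core, E_left), locus + max(core,
  E_right)] with E ~ Exponential(mean 2 Mb) per side and an always-swept
  core of ±1 Mb; exponential erosion models post-sweep recombination, and
  the core default mirrors the multi-megabase shared haplotype blocks
  observed at resistance loci. Poisson(2) private singletons per swept
  chromosome inject the rare-allele excess explicitly, so the negative
  Tajima's D contrast is not an artifact of the overwrite. Homozygous
  carriers receive two swept chromosomes, heterozygous one. The overwrite
  yields observed calls (previously masked entries inside a tract become
  the haplotype allele): the tract is the ground-truth object the
  screening stage is tested against. Carrier fractions are fractions of
  each population; when several backgrounds are layered, carriers are
  drawn from the samples not yet claimed.
* **Depth**: per-individual effort ~ Gamma(shape 10, mean 20); site depth
  ~ Poisson(effort × copy/2) with the copy number from the CNV spec inside
  its region, 2 elsewhere.
* **Admixture**: admixed alleles drawn from α·p_A + (1−α)·p_B using the
  sources' empirical frequencies; optional post-admixture drift as
  binomial resampling of the mixed frequency vector (2N draws per
  generation) — without drift the f3 signal is weak by design of the
  statistic.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: linked neutral variation with realistic LD decay
(neutral SNPs are independent given population frequencies), RAD-tag
clustering of SNPs and tag-level dropout (missingness is i.i.d., and
carrier tracts are fully observed), mutation-rate and recombination-map
realism, selection coefficients or sweep timing, overlapping generations
and migration. Background haplotypes are random mosaics rather than
segments of real genealogies, so between-background FST at the core is
higher than real backgrounds that share recent ancestry.

## Problem sizes in the verification suite

The simulated experiments run at 100–330 individuals and 5,000 SNPs
(10,000 for f3), ten seeds for recovery/localisation, twenty for FDR
calibration — sizes at which every expected signal is comfortably
detectable while the whole suite runs in minutes on one CPU. Recovery in
the two-background experiment is pooled over the ten seeds (500 simulated
homozygous carriers). The planted linkage-network check uses ~100-member
backgrounds: with subsets of ~30, single-individual r² = 1 matches between
private singletons dominate the histogram, which is the same small-sample
noise visible in real network analyses of small cohorts.

## Known limitations

* Tajima's D under heavy, non-uniform missingness depends on the modal-n
  convention; alternative conventions shift |D| slightly in sparse bins.
* The least-squares scan assumes an additive dosage effect and normal
  residuals; λ-recalibration corrects scale, not shape, of the null.
* The haplotype screen assumes the screen SNPs span a region where
  carriers are truly homozygous; screens much wider than the shared core
  lose carriers to the one-deviation rule.
* f3 on reduced-representation data is underpowered at small block counts;
  the block-count warning is a reminder, not a fix.
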