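# Methods

## Problem and scope

`feralsweep` implements a selective-sweep discovery and validation workflow
for multi-breed SNP cohorts of the kind produced by pooled whole-genome
resequencing of sheep populations: a target breed (e.g. a semi-feral Tibetan
population) is compared against a reference pool of breeds, the genome is
scanned for windows showing joint excess of population differentiation and
loss of heterozygosity, genes in and around the resulting regions become
candidates, and candidate variants are validated downstream by
genotype-phenotype association and qPCR expression analysis.  A seeded
synthetic-cohort generator supplies inputs with the statistical structure
the scans assume, so the whole pipeline is testable without any external
data.

## Sweep scan

**Window geometry.**  30-kb windows advancing in 15-kb steps (half overlap),
tiled from position 0 of every chromosome; the terminal window is truncated
at the chromosome end.  Truncated windows are retained and subject to the
same exclusion rule as full windows.  Windows with fewer than 50 cohort SNPs
are flagged `excluded`: they stay in the output table but contribute to no
threshold or Z-score.

**F_ST.**  Weir & Cockerham (1984) theta-hat with per-site variance
components `a` (between populations), `b` (between individuals within
populations) and `c` (within individuals), aggregated per window as a ratio
of averages, `sum(a) / sum(a+b+c)`.  Sites with fewer than one genotyped
individual per population contribute nothing.  Raw values may be slightly
negative from sampling noise; reports clamp to [0, 1] and keep the raw value
in a separate column.  The ratio-of-averages aggregation (rather than
averaging per-site ratios) is the standard choice for window scans because
per-site ratios are noisy and undefined at low-information sites.

**Pooled heterozygosity.**  `H_P = 2 Σp Σq / (Σp + Σq)²`, where `Σp` and
`Σq` are the sums of major- and minor-allele frequencies over every cohort
SNP site in the window, computed per population (major/minor assigned
within the population being scored, since the statistic is
population-specific).  `H_P` is bounded by 0.5, attained when `Σp = Σq`.
The loss statistic is `log2(H_P|reference / H_P|target)`; a zero target
`H_P` yields a `+inf` sentinel that automatically exceeds any threshold —
no pseudocount is invented.

**Thresholds and calling.**  For each statistic independently, the
`ceil(0.05 · N)` highest non-excluded windows are selected and the cutoff is
the smallest selected value, so boundary ties are included; a window is
called a sweep when it reaches *both* cutoffs.  Rank-based selection makes
the rule reproducible under ties and invariant to monotone rescaling of the
statistics.  Called windows that overlap or book-end are merged into
regions; 15-kb flanks are applied to the merged region (not per window) and
clipped to the chromosome; genes with at least 1 bp overlap of the flanked
interval are candidates.

**Diversity statistics.**  Per window and population the scan also reports
π (per-site `2p̂q̂·k/(k−1)` summed and divided by window length), Watterson's
θ (`S / (a_{k−1} · L)`), Tajima's D with the standard 1989 constants, and
SNP density.  With missing genotypes the allele count `k` varies by site;
the Tajima/Watterson constants use the mean non-missing allele count over
window sites rounded to the nearest integer, which equals `2N` for complete
data.  Z-scores standardize F_ST and the Hp log-ratio over non-excluded
windows with the sample (n−1) standard deviation.

## Population structure and LD

Pairwise breed distances come either from genome-wide Weir-Cockerham F_ST
(negatives clamped to zero for use as distances), from allele-sharing counts
(`Σ |dosage_i − dosage_j|` over sites called in both samples), or from mean
absolute allele-frequency differences.  Neighbor-joining (Saitou-Nei) and
Newick serialization are delegated to scikit-bio.  PCA follows the
EIGENSOFT convention: per-site mean centering, scaling by `sqrt(p̂(1−p̂))`,
per-site mean imputation of missing dosages, SVD, and a deterministic sign
convention (largest-magnitude loading positive).

Two-locus haplotype frequencies are estimated from unphased 3×3 genotype
tables by EM over the double-heterozygote phase ambiguity (tolerance 1e-10,
≤1000 iterations); all other genotype classes contribute unambiguous gamete
counts.  D, D′ and r² follow the usual normalizations
(`D′ = |D|/D_max`, `r² = D²/(pA qA pB qB)`).  r² between genotype columns is
always computed from EM haplotype frequencies (not the genotype-correlation
composite), matching Haploview semantics.  LD decay bins intra-chromosomal
pairs by physical distance after MAF ≥ 0.1 and per-site missingness ≤ 0.2
filters, with seeded subsampling to a pair budget; empty bins report NaN.
LD pruning mimics PLINK `--indep-pairwise 50 5 0.2`: within each 50-SNP
window (advancing 5 SNPs) the later-position member of any pair with
r² > 0.2 is removed until no offending pair remains; pruning is a fixed
point (re-running removes nothing).

## Association

Genotypes are coded relative to the analysed cohort's major allele
(ties broken by a supplied reference allele, else lexicographically):
additive AA/Aa/aa → 2/1/0, recessive → 1/0/0, dominant → 1/1/0.  Horn size
(length in cm, polled animals included at 0) is fit by OLS; horn shape is a
logistic regression of SHE (spiral, horizontally extended) versus TCF
(tightly close to the face), with polled, scurred and uncertain animals
excluded.  Age (years) and sex (single 0/1 indicator) are optional
covariates; rows with any missing field are dropped listwise.  Both fits
are statsmodels (OLS and Newton-Raphson Logit); complete separation and
post-deletion collinearity are reported as errors, not estimates.  The
scan runs the full SNP × model × outcome grid in deterministic order,
skipping dominant fits with a logged reason when the minor-homozygote class
is absent; monomorphic SNPs are removed up front.  Raw p-values are primary;
a Benjamini-Hochberg column is available as an explicitly optional extra.

## Expression

Technical replicates are averaged first; `ΔCt = Ct_target − Ct_control`
per sample; `ΔΔCt` subtracts the calibrator ΔCt and relative expression is
`2^−ΔΔCt`, so the calibrator reports exactly 1.0.  The calibrator may be a
single sample or a group, in which case the group's *mean* ΔCt is the
reference (configurable; the group mean is the default because normalizing
to "expression in the calibrator horn type" is naturally a group-level
statement).  Group comparisons use Welch's unequal-variance t-test on the
2^−ΔΔCt scale — the scale of the quantity being compared — and
expression-phenotype trends use Pearson correlation with a two-sided t test.

## Synthetic cohorts

`simulate_genotypes` draws, per site, an ancestral frequency p₀ and, per
population, a frequency from `Beta(p₀(1−F)/F, (1−p₀)(1−F)/F)` — the
Balding-Nichols model — then genotypes as Binomial(2, freq).  The model is
chosen over coalescent simulation because its parameter F equals the
expected F_ST, giving an analytic recovery target for the scan, and because
the window statistics under test do not require LD realism (LD-dependent
code is tested on explicitly constructed duplicated/shuffled columns
instead).  Two ancestral spectra are available: `uniform` on the configured
bounds (default; convenient for dense scans) and `neutral` with density
∝ 1/p, used by the equilibrium tests of π/θ and Tajima's D.  For the
neutral spectrum the lower bound must sit well below 1/(2n) of the sampled
population (the tests use 0.01 with 10 diploids) so that the sampled site
spectrum includes the rare variants the equilibrium expectations assume;
truncating higher depletes singletons and biases D upward.

Sweeps are injected by redrawing the target population's genotypes inside
the interval from near-fixation frequencies (default 0.98) of one
consistently chosen allele per site (the cohort-minor allele), producing
both excess differentiation and heterozygosity loss; other populations are
untouched.  Injection operates on frequencies, not haplotype tracts —
haplotype-length statistics are out of scope here, so tract structure is
unnecessary.

The scan preset uses three 5.1-Mb chromosomes with 36 000 sites
(≈2.4 SNPs/kb, so essentially every 30-kb window clears the 50-variant
exclusion, mirroring a dense resequencing panel), six populations of 10
samples (one target plus a five-breed reference pool), background F = 0.05
and three 60-kb sweeps.  These sizes keep a full scan under a few seconds
while leaving >1000 windows for stable top-5% thresholds.

Phenotypes follow the 182-animal field-cohort design: horn length =
intercept (18 cm) + 11.75 cm per major-allele copy + 1.2 cm/year of age +
6 cm for males + N(0, 8 cm), truncated at 0; shape is Bernoulli-SHE with
log-odds −1.5 + 4.0·[major homozygote]; categories follow the length bands
(0 → polled, ≤12 cm → scurred, else SHE/TCF by the shape draw).  The causal
MAF of 0.2 makes the major-allele homozygote the most common class, as in a
cohort dominated by the swept haplotype.  Ct tables mirror the 4 SHE /
4 TCF / 5 scurred qPCR design with technical triplicates, control Ct
~ N(20, 0.2), group ΔCt means (4.0 / 2.0 / 2.5) giving the SHE group the
lowest target-gene expression, biological sd 0.4 and replicate sd 0.1.

What the generator does *not* emulate: linkage disequilibrium and haplotype
structure, allele-frequency spectra shaped by real demography, genotyping
error, relatedness within breeds, and environmental covariance between age,
sex and genotype.  Passing tests therefore demonstrate correctness of the
statistics and of the discovery logic under the stated models — not
robustness to those real-data complications.

## Numerical and degenerate-input choices

* Missing genotypes (`./.` and half calls like `./1`) are treated as
  missing, excluded site-wise from allele counts, never imputed (except
  PCA's explicit mean imputation).
* MAF filtering uses all non-missing alleles over the whole cohort and is
  idempotent.
* Windows with no usable site yield NaN sentinels that propagate to an
  exclusion, never silently to zero.
* Thresholding requires ≥20 non-excluded windows; a constant statistic
  vector makes Z-transformation an error rather than a zero-division.
* EM starts from uniform haplotype frequencies; the double-heterozygote is
  the only ambiguous class, so convergence is near-immediate for tables
  without it.
* PLINK's pair-resolution rule is under-documented; we remove the
  later-position member of an offending pair.  This affects only tie-sets.
* All generators derive child seeds deterministically from the master seed;
  identical configuration implies byte-identical output files.

## Known limitations

* F_ST is the two-population Weir-Cockerham estimator; the multi-population
  generalization is not implemented (pairwise matrices cover the tree/PCA
  use cases).
* The per-window chromosome count convention (mean rounded `k`) is an
  approximation under heavy, uneven missingness.
* `ld_decay` enumerates pairs in Python and is intended for the
  ≤10⁵-pair budgets it defaults to, not genome-scale LD maps.
* Depth-based variant filtering belongs to upstream variant calling and is
  out of scope for genotype-only VCF input.
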