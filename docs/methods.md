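# Methods

## Scope and data model

`sojapop` analyses biallelic SNP panels from structured, predominantly
selfing plant populations. Genotypes are alternate-allele dosages
(0/1/2, −1 missing) in a samples × sites matrix; site coordinates keep the
VCF 1-based convention, while every interval the package emits (sweep
regions, SALs, gene spans) is 0-based half-open, BED-style. "Touching"
intervals (shared boundary coordinate) merge; a gene that only shares an
interval's end coordinate does not overlap it.

## Filtering and LD pruning

Genotypes failing per-sample depth (DP < 3) or genotype quality (GQ ≤ 20)
are set missing first, but only when the VCF declares those FORMAT fields.
Sites are then kept when the missing fraction is < 0.5 and the minor-allele
frequency (computed over non-missing alleles) is ≥ 0.05; both boundary rules
are inclusive on the keep side for MAF and on the drop side for missingness.
LD pruning mirrors PLINK `--indep-pairwise 50 10 0.1`: inside each 50-SNP
window advanced by 10 per chromosome, any retained pair with squared dosage
correlation above 0.1 (missing entries pairwise-deleted) loses the
lower-MAF member (ties: the later site). The sweep repeats over the
survivors until nothing is removed. In structured panels, sites from
different original windows become neighbours after a pass and can exceed the
threshold, so a single pass is not a fixpoint; iterating makes pruning
idempotent at the cost of a somewhat smaller retained set.

## Windowed diversity, F_ST and sweep calling

Per-site diversity is the unbiased estimator π = 2·c_ref·c_alt/(n(n−1)) on
non-missing allele counts; window π sums site values over 500 kb windows
stepped by 100 kb and divides by the nominal window span (the last,
truncated window per chromosome is still normalized by 500 kb — the fixed-
window convention, slightly deflating diversity there). Windowed F_ST is
ratio-of-sums over the per-site two-population Weir–Cockerham (1984)
variance components computed from sample sizes, allele frequencies and
observed heterozygosity; negative windowed values are retained because the
sweep thresholds are empirical quantiles and need the full distribution.
Windows with fewer than 10 SNPs or zero diversity in either group are
flagged excluded — diversity ratios there reflect data sparsity, not
selection. Sweep candidates must lie in the upper `fst_tail` (default 5%)
of the F_ST distribution AND in either one-sided `pi_tail` (default 5%) of
ln(π_A/π_B), with quantiles interpolated linearly (type 7) over the
non-excluded windows of that comparison only; candidates merge per
chromosome and per diversity-loss direction. Windows from opposite π tails
are never merged.

## Structure inference

Genetic distance is the allele-sharing p-distance, mean |g_i − g_j|/2 over
sites non-missing in both samples — chosen as the assumption-free option
since survey pipelines differ in their distance models; location-level
distances average over cross-location sample pairs. Neighbor-joining uses
scikit-bio's Saitou–Nei implementation with negative branch lengths clamped
to zero; on additive metrics it reproduces the generating tree exactly,
which is the property the tests assert. PCA mean-imputes missing dosages
per site, centres, scales by √(p(1−p)) and takes the SVD; monomorphic and
all-missing sites are dropped.

Ancestry estimation maximizes the binomial admixture likelihood
Σ_il [g_il ln(Σ_k q_ik p_kl) + (2−g_il) ln(1−Σ_k q_ik p_kl)] by plain EM
block updates of Q (rows on the simplex) and P, skipping missing entries.
This is the same objective ADMIXTURE optimizes; its quasi-Newton
acceleration is omitted because desk-scale panels (≲ 200 samples, ≲ few
thousand pruned SNPs) converge in seconds. The log-likelihood is
non-decreasing across iterations (EM guarantee; asserted in tests to 1e-6
relative). Frequencies are floored at 1e-12 to keep the likelihood finite.
K is selected by masked-entry cross-validation: observed genotype entries
are partitioned uniformly at random into 5 disjoint folds; each fold is set
missing, the model refit, and the hidden dosages predicted as 2·Σ_k q_ik
p_kl; the error is the mean squared error (binomial deviance available via
`metric="deviance"`). Under-K fits underpredict the hidden entries of
diverged groups and over-K fits chase noise, so the error is minimized at
the simulated K in practice.

## Isolation by distance

Geographic distances are haversine great-circle distances with Earth radius
6371.0088 km. The Mantel statistic is the Pearson correlation over the
strict lower triangle; the null distribution jointly permutes rows and
columns of the second matrix with a seeded generator. The test is one-sided
(upper tail) because isolation by distance predicts positive correlation,
with the add-one convention p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm) and
9999 permutations by default, so the smallest attainable p is 1e-4.

## Genotype–environment association and SALs

Each SNP's dosage is regressed on an intercept, the standardized
environmental variable, and `n_latent` latent factors taken as the top
principal components of the LD-pruned genotype matrix (default
`n_latent` = best K − 1). This realizes the latent-factor association
contract — per-SNP environmental tests adjusted for genome-wide structure —
as PC-covariate least squares with genomic-control recalibration rather
than a re-implementation of a specific mixed-model estimator. The squared
t-statistic of the environment coefficient is divided by
λ = median(z²)/median(F(1, dof)) and referred to F(1, dof). The F
reference matters: at n ≈ 200 the squared-t tail is ~1.7× heavier than
χ²₁ at Bonferroni-scale quantiles, and using χ²₁ measurably breaks null
calibration. Benjamini–Hochberg controls FDR at q < 0.05; each significant
SNP contributes a ±100 kb interval clipped to the chromosome, and
overlapping or touching intervals merge into SALs whose peak is the
contained SNP with minimal q. Genes from a GFF3 overlap a SAL when their
half-open spans share ≥ 1 bp; an optional user-supplied mapping file
attaches homolog annotations.

Because the environmental gradient is nearly collinear with the leading
structure axes, the effective signal for the environment coefficient is the
component of the environment orthogonal to the PCs (local deviations from
the regional cline). Median-based λ recalibration centres the null but
cannot remove per-SNP location-level random effects from the extreme tail,
so the realized FDR among structured alternatives can exceed the nominal
level even when the permuted-environment null is clean; this is a known
cost of two-step latent-factor corrections and is stated as a limitation.

## Synthetic-data generator

The generator emulates the survey structure the analyses assume, at desk
scale. Defaults (units in parentheses):

* 3 groups × 5 locations × 5 samples; 4 chromosomes × 10 Mb; 20 000 SNPs.
* `fst_divergence` = 0.30: Balding–Nichols group frequencies
  p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral p ~ U(0.05, 0.95).
* `selfing_fis` = 0.95: genotypes drawn with inbreeding-adjusted
  probabilities (observed heterozygosity < 10% of Hardy–Weinberg, as
  expected for a predominantly selfing species).
* Geography: group latitude bands centred at 25/35/45 °N (about the
  22–48 °N span of the real eco-regions), locations spaced evenly across a
  ±3.5° band per group with 0.5° jitter — survey-style placement that
  guarantees within-group latitudinal spread.
* Environment: annual mean temperature (°C) and precipitation (mm) decrease
  linearly with latitude plus location noise (`env_noise_sd`, default 2.0;
  temperature noise is 1.5× this because local temperature deviations are
  elevation-dominated).
* Isolation by distance: per-SNP within-group latitudinal logit gradients
  (sd 0.1) plus location noise (sd 0.05). These scales are deliberately
  small relative to plausible adaptive effects: an IBD gradient of the same
  magnitude as the environmental response would be statistically
  indistinguishable from selection.
* Sweeps: `n_sweeps` = 3 non-overlapping 1 Mb intervals; within the
  affected group, frequencies move toward fixation so p(1−p) is scaled by
  1 − `sweep_diversity_reduction` (default 0.9).
* Adaptive loci: `n_adaptive_loci` = 30, alternating between temperature
  and precipitation (latitude is a proxy coordinate, not a selective
  agent); at these loci selection overwhelms drift, so the local frequency
  is built from the ancestral logit plus `env_effect` × standardized
  environment rather than from the drifted group frequency — keeping the
  dose–response away from the [0.01, 0.99] clamp that otherwise pins
  extreme-group frequencies.
* All frequencies are clamped to [0.01, 0.99] after any shift; one
  `numpy.random.Generator` seeded once drives every draw in a fixed order,
  so equal seeds give byte-identical output files.

What the generator does **not** emulate: linkage disequilibrium from
recombination (sites are independent given the local frequency), mutation-
rate heterogeneity, genotyping-depth-driven missingness patterns, admixed
individuals, and demographic time-depth. Passing tests therefore show that
the estimators and calling rules behave correctly under the assumed
sampling model, not that the pipeline is robust to every artefact of real
reduced-representation data.

## Problem sizes and test design

The test suite runs the statistical recovery checks at desk scale chosen as
the package's own validation conditions: sweep recovery over 20 replicates
of 195 samples × 6000 SNPs on 2 × 5 Mb chromosomes; K-selection over 10
replicates of 72 samples with 5-fold masked CV over K = 2..6 (the API
default range is 2..10); association calibration and power on 192-sample,
24-location panels with `env_effect` = 4.0 ("strong": the allele frequency
nearly switches across the environmental range); Mantel calibration over
1000 null tests at 199 permutations, where rejection at p ≤ 0.05 has exact
level 10/200 = 0.05. Oracles are independent of the code paths they check:
a scalar straight-from-the-formula Weir–Cockerham implementation, Monte-
Carlo expectations for the Balding–Nichols model, brute-force interval
overlap enumeration, additive-metric round trips for neighbor-joining, and
scikit-bio's Mantel statistic.

## Known limitations

* The admixture EM is unaccelerated; thousands of samples or tens of
  thousands of pruned SNPs would need the quasi-Newton speedups it omits.
* The two-step latent-factor association (PCs, then OLS) sacrifices signal
  collinear with the structure axes and does not model location-level
  random effects; λ recalibration restores the null median, not the tail.
* p-distance trees are not model-corrected (no multiple-hit correction);
  fine for within-species divergence, inappropriate for deep phylogenies.
* The windowed scan assumes contig lengths are declared (VCF `##contig`
  headers or simulator metadata); without them the last window ends at the
  last observed SNP.
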