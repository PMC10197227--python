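# Methods

`pstfst` implements a Pst–Fst divergence analysis for common-garden studies
of structured populations: it asks, per quantitative trait, whether
phenotypic differentiation among groups exceeds what neutral genetic drift
(measured by Fst at neutral SNPs) can explain. This note documents the
models, the estimators, the synthetic-data generator used for validation,
and the numerical and design choices.

## The hierarchical trait model and Pst

For a trait measured on individuals nested in populations nested in the
compared units (two regions, or the native/non-native range split), the
model is the Gaussian variance-components model

    y_i = mu + a_{u(i)} + b_{p(i)} + e_i,
    a_u ~ N(0, sigma2_B),  b_p ~ N(0, sigma2_P),  e_i ~ N(0, sigma2_e).

Pst is the phenotypic analogue of Qst:

    Pst = sigma2_B / (sigma2_B + 2 h2 sigma2_W),

with heritability `h2 = 1` by default (the conventional assumption when
only phenotypes from a common garden are available; Pst then upper-bounds
the genetic signal and confounds any residual plastic divergence). The
`2 h2` form of the denominator is used, so results at `h2 = 1` match the
standard Qst convention and changing `h2` scales the denominator the way
the Qst literature expects.

Two conventions for the within-group variance `sigma2_W` are implemented:

* `residual-plus-population` (default): `sigma2_W = sigma2_P + sigma2_e`,
  i.e. all phenotypic variance below the compared level;
* `residual-only`: `sigma2_W = sigma2_e`.

Both are defensible readings of "within-population variance" when the
compared level sits above the population level; the default treats
everything inside a compared unit as within-group. The switch is
`PstModelConfig.sigma_w_convention`.

### Gibbs sampler

Priors are the conventional vague conjugate choices: `mu ~ N(0, 1e6)` and
independent Inverse-Gamma(0.001, 0.001) on the three variances. All full
conditionals are standard (normal for `mu`, `a`, `b`; inverse-gamma for
the variances), so the sampler is a plain conjugate Gibbs scheme. Chains
are advanced in lockstep (vectorised over chains) from overdispersed
starting points: each chain's variances are method-of-moments anchors
scaled by a log-uniform factor in [1e-2, 1e2]. Defaults are 5 chains of
50,000 post-burn-in iterations after a burn-in of 1,000; draws are pooled
with no thinning. Split-chain Gelman–Rubin R-hat is reported per variance
component; R-hat > 1.1 triggers a log warning. A single integer seed makes
runs bit-reproducible.

**Two-unit caveat.** For the range split (and any pairwise comparison) the
between-unit variance is informed by only two group effects, so its
posterior is unavoidably prior-sensitive: the conditional for `sigma2_B`
is IG(1.001, s), whose right tail is heavy (its mean is orders of
magnitude above `s`). On the bounded Pst scale the effect is milder but
real: posterior means of Pst scatter around the generating value with
typical absolute errors of ~0.1 on replicate fixtures, and credible
intervals are wide. The interval-based classification below is the
intended use; point estimates of Pst from two units should not be
over-interpreted. With more units (e.g. six regions jointly) the posterior
concentrates normally.

### Decision rule

Per posterior draw, the difference Pst − Fst is formed, either against a
scalar mean Fst or against bootstrap Fst draws (paired by uniform
resampling, which propagates Fst uncertainty). The equal-tailed interval
at mass 0.975 (quantiles 0.0125/0.9875) classifies the trait:

* interval entirely above zero → **divergent** selection indicated;
* entirely below zero → **stabilizing**;
* otherwise → **drift-consistent**.

The 0.975 mass follows the convention of reporting "97.5% credibility
intervals" in this literature; if that phrasing is read as a 95% interval
bounded at the 2.5/97.5 percentiles, set `interval_mass = 0.95` — the
classification of clear-cut traits is insensitive to the choice.

## Site filtering

The analysis-ready SNP set is produced by three rules applied in a fixed
order: (1) drop indels and non-biallelic records; (2) require genotyping
proportion ≥ 0.9 within **every** population (computed over individuals in
the population map; unmapped samples are dropped with a warning, mirroring
a keep-file); (3) keep sites whose global minor allele frequency is
**strictly** greater than 0.05 (a site at exactly 0.05 is removed). The
filter log records removals per rule and the operation is idempotent. The
rule order is a convention; survivor sets can differ slightly under other
orders, which is why the log is part of the output.

## Neutral-structure statistics

* **Weir–Cockerham theta.** Per-locus variance components a (among
  populations), b (among individuals within populations), c (within
  individuals) from genotype counts with unequal sample sizes; the
  multi-locus estimate is the ratio of sums `sum(a) / sum(a+b+c)` over
  loci with non-zero total variance. 95% CIs come from a percentile
  bootstrap over loci (default 1,000 replicates). Pairwise comparisons
  treat the two units as the "population" level of the model.
* **Diversity.** Ho is the heterozygote fraction, He the gene diversity
  `2p(1-p)` (a `2n/(2n-1)` unbiased variant is available), both averaged
  over loci polymorphic within the unit by default; F_IS is the
  ratio-of-sums `1 − sum(Ho)/sum(He)` over polymorphic loci. Allelic
  richness rarefies each locus to a common allele-sample size g (the
  smallest per-locus genotyped allele count across units unless set):
  `Ar = sum_a [1 − C(2N−n_a, g)/C(2N, g)]`, computed with log-gamma for
  stability and validated against exhaustive subsample enumeration.
* **LD-Ne.** For each pair of loci passing an allele-frequency screen
  (default 0.05), the Burrows composite disequilibrium is computed over
  pairwise-complete individuals, multiplied by the standard `n/(n-1)`
  small-sample factor, squared, and standardised by `p(1-p)q(1-q)`. The
  weighted mean (weights = pairwise sample size S) is corrected by the
  no-drift sampling expectation (`1/S + 3.19/S^2` for S ≥ 30, else
  `0.0018 + 0.907/S + 4.44/S^2`) and inverted through the random-mating
  drift relation `Ne = (1/3 + sqrt(1/9 − 2.76 r2))/(2 r2)`. A
  non-positive drift signal yields an infinite estimate — the expected
  outcome when the true Ne is large relative to sample size. A
  delete-one-locus jackknife CI is optional. All pairwise quantities are
  computed by masked matrix products, so missing genotypes are handled
  per pair without loops.

## Outlier scans and the neutral set

* **Trimmed chi-square scan.** The per-locus Fst *without* the
  finite-sample correction (`a = (nbar/nc) s2` over total) is fitted, on
  the trim interior (default 5%/5%), by a scaled chi-square: F ~ Fbar *
  chisq(df)/df with df estimated by maximum likelihood under truncation
  to the trim window. Right-tail p-values are converted to
  Benjamini–Hochberg q-values; loci with pooled He < 0.10 are excluded
  from both fit and calls (low-diversity loci have unstable Fst). BH is
  used rather than Storey's estimator because it is parameter-free; this
  makes the scan slightly conservative.
* **PC-regression scan.** Missing dosages are mean-imputed, loci centred
  and scaled, and the leading K principal components (default: number of
  units − 1) computed over individuals. Each locus is regressed on the K
  component scores; the K z-scores are combined into a Mahalanobis
  distance (robust MinCovDet covariance, falling back to the classical
  estimate when the robust fit is degenerate), divided by a genomic
  inflation factor (median distance / chisq_K median) and referred to
  chisq(K); BH q-values follow.
* **External results** (e.g. a Bayesian allele-frequency method run
  elsewhere) can be imported as per-locus flags and merged.
* **Consensus.** Default rule `any`: a locus flagged by at least one
  method is an outlier; the neutral set is the complement, and the two
  sets partition the panel. `at-least-2` and `all` are available. The
  pipeline enforces that Fst values fed to the Pst comparisons are
  computed on the neutral set (override flag `allow_full_set_fst`).

Both scans flag ≤ 1% of loci at q < 0.05 on null fixtures; with 2% of
loci simulated at 10× the background drift, the trimmed-chi-square scan
detects ≳ 80% and the PC scan ≳ 85% of spiked loci surviving the site
filters (the global MAF rule removes near-fixed spiked loci before any
scan sees them).

## Synthetic-data generator

Genotypes follow a two-level Balding–Nichols model: per locus, an
ancestral frequency is drawn (uniform MAF in (0.05, 0.5], random minor
allele), each region's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) with
drift parameter `F_neutral` — so the expected Weir–Cockerham theta among
regions equals F — and populations within a region take a second, weaker
Beta draw (`F_pop`, default 0.01), mimicking the limited within-range
substructure of a recently spread invader. Genotypes are Binomial(2,
freq); missingness is completely at random. Defaults emulate a six-region
design of 24 individuals per region at ~2,000 biallelic RAD SNPs with
region-level F in the low-moderate range; the first third of regions is
labelled native. A configurable minority of loci can be drawn at an
elevated drift parameter to stand in for selected loci — elevation of F,
not explicit selection coefficients, which is sufficient to exercise the
scans.

Traits are Gaussian draws from exactly the hierarchical model the sampler
fits, so the recorded truth includes the exact Pst implied by the
configured variances. An optional `range_effect` adds a fixed mean shift
between ranges: a region-level variance alone cannot generate a
between-range contrast, so a demo trait "under divergent selection
between ranges" is simulated as an explicit shift — which is also what
such selection produces phenotypically.

What the generator does **not** emulate: linkage (loci are exchangeable
and unlinked), coalescent/demographic history (no bottlenecks or
admixture trajectories), genotyping-error structure (missingness is MCAR,
real RAD dropout is allele-frequency-dependent), non-Gaussian traits
(counts are simulated as Gaussian), and phenotyping attrition (designs
are balanced). Passing tests therefore demonstrate estimator correctness
and calibration under the stated models, not robustness to these real-data
features.

## Validation fixtures and problem sizes

The test suite and `scripts/acceptance.py` use: 20 replicate six-region
fixtures (24 diploids, 2,000 loci) for theta recovery at F = 0.09
(tolerance ±0.015, bootstrap coverage ≥ 18/20); a 2 × 5 × 30 known-truth
fixture for Pst recovery at 5 chains × 5,000 iterations; 100 (tests) / 50
(script) reduced-scale replicates (2 × 5 × 10, 3 chains × 2,000) for null
calibration of the decision rule; four spiked 2,000-locus fixtures for
scan power; and 50 (tests) / 30 (script) Wright–Fisher fixtures (true
Ne = 50, 25 generations, 24 sampled, 200 loci) for LD-Ne. These sizes
were chosen to give stable Monte-Carlo estimates at interactive runtimes;
the full-scale defaults (50,000 iterations, 1,000 bootstrap replicates)
remain the package defaults.

## Known limitations

* Two-unit Pst posteriors are prior-sensitive (see above); only the
  interval classification is calibrated, and the null calibration test
  shows the divergent call is conservative in this regime.
* The trimmed-chi-square scan assumes a single background differentiation
  regime; strong hierarchical structure would need the PC scan (which
  absorbs structure into its components) or an explicit hierarchical null.
* LD-Ne assumes random mating, unlinked loci and a closed population;
  estimates are reported as infinite whenever the drift signal is not
  separable from sampling noise, rather than as arbitrary large numbers.
* Fst supplied to a comparison is a point value (or bootstrap draws); no
  joint genotype-phenotype posterior is attempted.
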