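# Methods

## Model

`regionpls` estimates a two-block latent-variable path model linking a set of
SNP dosages to a set of correlated anthropometric traits. Each block of
observed ("manifest") variables — the *P* dosage columns of a genomic window
or SNP set, and the trait columns waist (cm), hip (cm), BMI (kg/m²) — is
summarized by a latent score ξ, a weighted sum of its standardized manifests.
The inner model is a single directed path

    ξ_traits = β21 · ξ_region + ζ,

so β21 is the standardized regional (or polygenic) effect on the latent
"body shape" phenotype and R² = β21² is the variance it explains. Loadings λ
are manifest–latent Pearson correlations; the product λ_j · β21 is the
standardized indirect effect of SNP *j* on body shape.

## Estimation

The fit uses the classical Lohmöller alternation: (i) latent scores from the
current outer weights, rescaled to unit variance; (ii) an inner approximation
of each latent from its neighbours (centroid scheme by default — the sign of
the latent correlation times the neighbour score; factorial and path schemes
are selectable); (iii) outer-weight update (mode A, reflective: covariance of
each manifest with the inner estimate; mode B, formative: multiple regression
of the inner estimate on the block). Iteration stops when the largest
absolute outer-weight change falls below `tol` (default 1e-6, `max_iter`
300). Path coefficients are then OLS regressions among the latent scores.

Because the manifests are standardized, everything except the latent scores
is a function of the manifest correlation matrix alone. The implementation
exploits this: the same iteration code runs on a single correlation matrix or
on a batch of them (one per bootstrap resample or permutation), which is what
makes resampling inference at B in the thousands cheap.

Numerical choices:

- **Outer-weight initialization**: ones per block — deterministic; there is
  no randomness anywhere in the fit.
- **Sign handling.** PLS latent directions are identified only up to sign,
  and with near-null data the centroid update can flip both blocks jointly on
  every pass (all estimands invariant), which would stall a naive convergence
  check. Convergence is therefore assessed modulo per-block sign; the final
  sign is fixed by requiring each block's loading sum to be ≥ 0. Flipping
  every manifest of one block consequently leaves its loadings unchanged and
  reverses β21, which is the natural behaviour for an orientation convention.
- **Standardization** uses the sample (n−1) standard deviation; a
  zero-variance column is an error naming the column; missing genotype
  entries are mean-imputed per SNP before standardization.
- **Covariate adjustment** (sex, age) residualizes every manifest variable on
  [1, covariates] before standardization. The alternative — entering the
  covariates as an extra exogenous block — was considered; residualization
  was chosen because it keeps the two-block structure of the scan model
  intact and makes "adjusted" and "unadjusted" fits directly comparable.

## Bootstrap inference

The sampling distribution of PLS parameters has no closed form, so
significance is assessed by a non-parametric bootstrap: `n_boot` resamples of
individuals with replacement (same n as the original sample; default B =
5000), the full pipeline re-run per resample, and a two-sided normal test
z = θ̂/SE_boot, p = 2(1 − Φ(|z|)). Resamples are sign-aligned block-wise to
the original fit before standard errors are taken. A resample containing a
zero-variance column is redrawn (warned when > 1% of resamples needed it).
Everything is reproducible given a seed.

A caveat that matters for simulation studies: β̂21 is obtained by weights
that maximize cross-block covariance, so under a true null its magnitude is
biased away from zero, and the bootstrap normal test inherits that bias — in
our null simulations it rejects at ~3× the nominal 5% level. For this reason
the simulation drivers default to a **permutation test** of β21 (genotype
rows permuted against trait rows; p = (1 + #{|β*| ≥ |β̂|})/(1 + K)), which is
calibrated by construction. The bootstrap remains the inferential engine for
data analysis (`scan`, `polygenic`, `bootstrap` commands), where the
estimate-centred standard error and confidence intervals are the quantities
of interest; the switch is `test="bootstrap" | "permutation"` on the
simulation drivers. Note a K-permutation p-value cannot fall below
1/(K+1), so testing at α = 0.001 needs K ≥ 1999.

## Scan statistic and multiplicity

A region of m SNPs is scanned with sliding windows of w SNPs, step 1
(m − w + 1 windows, 1-based inclusive coordinates as in VCF). Each window is
fitted as the two-block model above and β21 is tested; monomorphic SNPs are
dropped within a window (a window is skipped only if no SNP remains). The
per-region level is Bonferroni-corrected over windows, α/(m − w + 1) — the
conservative standard for region-based scans. Whether p-values should be
further corrected jointly across window sizes 1–15 is left to the user; the
operation accepts any window count, so α/255 for the full size grid on a
24-SNP region is one call away.

The single-SNP single-trait OLS baseline (statsmodels, two-sided t tests)
mirrors the conventional GWAS analysis the latent model is compared against.

## Polygenic scores

For a SNP set drawn from different genomic regions, the SNP-block latent
score is the polygenic risk score (PRS): risk alleles weighted by their
loadings rather than counted. The trait-block score is the body-shape score
(BSS). Both are unit-variance by construction; `body_shape_score` offers an
affine rescaling for reporting, and `weighted_allele_score` offers an
allele-count scale Σ (λ_j/Σλ)·g_ij bounded by [0, 2], matching conventions
that report a PRS as a weighted average of allele counts. Body types are a
3×3 grid of BMI strata × sex-specific WHR strata (codes 1–9, labels Chilli …
Big apple); the default cuts — BMI 25/30, WHR 0.90/1.00 (men) and 0.80/0.85
(women) — are configurable conventions, with half-open lower-inclusive
intervals so a value on a cut goes to the upper stratum.

## Synthetic-data generator

No cohort data are distributable, so the simulation engine generates both
sides:

- **Genotypes.** A first-order Markov model over 24 loci: each haplotype's
  risk-allele indicator at locus j+1 is correlated with locus j at a target
  r (default 0.8), giving the geometric LD decay of short candidate regions;
  genotypes are unions of two independent haplotypes, hence Hardy–Weinberg
  proportions. Adjacent allele frequencies are drawn as a constrained random
  walk, uniform over the part of (0.1, 0.5) for which the target r is
  attainable for a Bernoulli pair — mirroring the fact that strongly
  correlated markers in real LD blocks have similar frequencies. A
  user-requested infeasible correlation is clipped to the attainable bound
  with a warning.
- **Phenotypes.** (waist, hip, BMI) are trivariate normal for an
  "apple-shaped" reference stratum: means (100, 104, 28), SDs (5, 4.5, 1.4),
  correlations waist–hip 0.80, waist–BMI 0.80, hip–BMI 0.75. The SDs are
  within-stratum spreads: a single body-shape stratum confines BMI to a band
  of a few kg/m², so its SD is ~1.4, not the population-scale ~3.5 — the
  scale at which a per-allele effect of 0.1–0.3 kg/m² is detectable at the
  stated sample sizes. Each copy of the causal allele (SNP 6 of 24 by
  default) adds δ kg/m² to BMI and b·δ cm to waist (b = 1.8 cm per kg/m²,
  the waist change per BMI unit at fixed hip); hip is untouched. δ = 0 is
  the null model exactly.

What the generator does **not** emulate: genotyping error and missingness
patterns, population stratification, haplotype blocks with recombination
hotspots (LD decays geometrically rather than in blocks), case-cohort
ascertainment, and non-normal trait tails. Passing simulation tests
therefore demonstrate calibration and power under idealized LD and
normality, not robustness to those artefacts.

## Simulation study sizes

The type-I-error run uses 1000 replicates of n = 1000 with a K = 500
permutation test at α = 0.05 (the Monte-Carlo SE of the rate is then 0.0069);
the power run uses 200 replicates of n = 4500 with K = 1999 at α = 0.001.
These replicate counts keep a full study in the minutes range on one CPU;
the full 10,000-replicate, B = 5000 setting is reachable through the same
functions or the YAML grid (`n_reps`, `n_boot`).

## Known limitations

- The bootstrap normal test for β21 is anticonservative under the null (see
  above); treat scan p-values near a threshold with care, or use the
  permutation switch.
- Mode-B (formative) blocks require a well-conditioned within-block
  correlation matrix; heavy LD can make the regression step unstable.
- The per-region α correction is plain Bonferroni; overlapping windows make
  it conservative.
- Latent scores, PRS and BSS are sample-standardized: they are comparable
  within a fitted sample, not across cohorts without an anchoring rule.
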