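# Methods

## Setting and model

The package implements a summary-level causal screen with three linked
two-sample Mendelian randomisation (MR) analyses.  Throughout, a
"trait" is a set of per-variant GWAS association records
(effect/other allele, EAF, beta, SE, p, N); quantitative traits are in
SD units and binary traits on the log-odds scale, so `exp(beta)` is an
odds ratio per SD (OR_SD).  The two-sample assumption — exposure and
outcome effects estimated in non-overlapping samples — is taken at
face value everywhere; variances of derived quantities treat the two
inputs as independent.

### Estimators

* **Wald ratio** (single instrument): `by/bx`, first-order delta SE
  `sy/|bx|`.  No second-order correction is applied; the screen's
  single-IV instruments are strong (F ≫ 10), where the correction is
  negligible.
* **IVW** fixed/random: weighted no-intercept regression, weights
  `1/sy²`.  The random-effects SE uses a multiplicative
  overdispersion factor `sqrt(max(1, Q/(n-1)))`, so RE = FE under
  homogeneity.  P-values are two-sided normal.
* **Cochran's Q** uses first-order ratio weights `(bx/sy)²`, making Q
  identical to the weighted residual sum of squares of the IVW fit and
  exactly chi-square(n−1) under the null when instruments are strong.
* **MR-Egger** orients exposure betas non-negative, fits a weighted
  regression with intercept, and scales SEs by the (unfloored)
  weighted residual SD with a t(n−2) reference — the convention of the
  standard two-sample-MR tooling.  The intercept test is the
  directional-pleiotropy gate.
* **Median/mode estimators**: interpolated (weighted) median of Wald
  ratios; mode of a Gaussian-kernel density with a modified Silverman
  bandwidth `0.9·min(sd, mad)·n^(−1/5)` scaled by `bandwidth_factor`
  (default 1).  SEs come from a seeded parametric bootstrap (default
  1000 draws); weighted variants use full delta-method ratio variances
  `sy²/bx² + by²·sx²/bx⁴` as inverse weights.
* **Maximum likelihood** profiles out the latent per-SNP exposure
  effects from the bivariate-normal likelihood and optimises the
  single slope by Brent's method (xtol 1e-10, bounded fallback); the
  SE comes from the numerical curvature of the profile deviance.
* **MVMR-IVW**: weighted multivariable no-intercept regression.
  Conditional instrument strength per exposure follows the two-sample
  conditional F construction — an errors-adjusted weighted regression
  of that exposure's betas on the others', with Q divided by
  L−K+1 — iterating the weight/coefficient update to convergence.  The
  modified Q uses weights `1/(sy² + θ'Σ_j θ)` with per-variant genetic
  covariance `Σ_j[k,l] = ρ_kl·se_kj·se_lj` built from the phenotypic
  correlation matrix; df = L−K.  Exact collinearity is reported as a
  flag (pseudo-inverse fit) rather than an exception so degenerate
  designs still produce the diagnostics that route them away.
* **Phenotypic correlation** between exposures is estimated from the
  correlation of z-scores over variants null (p > 0.01) in every
  trait.  That conditioning clips the z tails and attenuates the
  correlation, so the estimate is de-attenuated by numerically
  inverting the doubly-truncated bivariate-normal moment
  (Gauss-Legendre quadrature + Brent root find).  Fewer than 1000
  overlapping null variants triggers an identity fallback with a
  warning.
* **Colocalisation** is the standard single-causal-variant enumeration
  over H0–H4 from Wakefield log-ABFs, computed entirely in log space
  (log-sum-exp), so |z| up to 200 cannot overflow.  Prior effect SDs:
  0.20 (SD scale) for quantitative traits, 0.15 (log-odds) for binary.
  Priors scale with locus size (`p1 = p2 = 1/(10·nSNP)`,
  `p12 = p1/10`); the p12 sensitivity curve uses 8 log-spaced points
  from 1e-8 to min(p1, p2) by default.
* **Mediation**: difference method `indirect = total − direct` with
  independence-assumption SE `sqrt(se_tot² + se_dir²)` (the total and
  direct estimates share data, so this is an approximation; it is
  conservative and flagged in the result), or product method
  `β_EM·β_MO` with product delta SE.  Proportion mediated divides by
  the total effect, delta-method CI, no bootstrap.  Per-mediator
  product effects are never summed across mediators: correlated
  mediators (e.g. one metabolic pathway) would double-count.

### Pipeline gates

A pair survives a stage only if it clears, in order: Bonferroni
significance (stage-wide test count), no significant heterogeneity
(Q p < 0.05), no directional pleiotropy (Egger intercept p < 0.05,
≥3 IVs), no leave-one-out driver SNP (an otherwise-significant
association that a single SNP's removal renders p > 0.05), no
significant bidirectional (reverse-MR) association, and — in Stage 2 —
sign-consistent replication at the replication-wise Bonferroni level
and PP_shared > 0.8 in at least one IV region.  Stage 3 additionally
applies the sign-consistency filter
(`sgn(β_EM·β_MO) = sgn(β_total)`), removes exposure–mediator
instrument overlaps (r² ≥ 0.01 within 0.5 Mb) from the larger-sample
GWAS, and accepts a user-supplied exclusion list of known-pleiotropic
variants, rerunning affected estimates after removal — the screen's
programmatic stand-in for a manual pleiotropy-catalogue check.

Harmonisation aligns outcome records to the exposure's effect allele
by direct match, allele swap (beta negated, EAF complemented) or
strand complement; palindromic (A/T, C/G) variants with MAF > 0.42 in
either study are ambiguous and dropped, the rest are oriented by EAF
concordance (nearest of `eaf_out` and `1−eaf_out` to `eaf_exp`; exact
ties dropped).  Coordinates are 1-based GRCh37; all windows are closed
intervals on |Δpos|.  Clumping is greedy by ascending p (ties: smaller
position, then lexicographic id) with pruning at r² ≥ 0.01 within
0.5 Mb against the reference panel; multivariable reclumping ranks
each variant by its minimum p across the traits.

## Synthetic data generator

`metabomr.synth` emulates the screen's data regime, not any specific
cohort:

* **Reference panel**: block-diagonal LD from a latent Gaussian copula
  thresholded to haplotypes.  One minor-allele frequency is drawn per
  block (variants in tight LD share frequencies in real panels), and
  the latent correlation is calibrated by tetrachoric inversion so the
  *dosage-level* correlation equals the requested `within_block_r` —
  naive thresholding would attenuate it.  Blocks sit pairwise on
  chromosomes 1–22, 2 Mb apart (beyond the clumping window), with the
  first chromosome-6 block placed inside the MHC window so region
  exclusion is exercisable.
* **Triads**: the exposure is polygenic (default 50 causal variants,
  h² = 0.25, GWAS n = 50,000 — instruments with F ≈ 250, the
  strong-instrument regime of consortium obesity GWAS).  Metabolites
  are standardised, driven by `β_EM ×` exposure plus a couple of
  strong cis-like loci (default 2 loci, h² = 0.10) in a GWAS of
  n = 8,000 — the scale of plasma-metabolomics cohorts, with the
  deliberate consequence that exposure variants are *not* genome-wide
  significant in the metabolite GWAS, so mediator instruments stay
  clean.  The binary outcome combines the direct exposure path, the
  metabolite-mediated path and 10 susceptibility loci of its own
  (h² = 0.05 on the log-odds scale) that act as reverse-MR
  instruments.  Marginal effects follow block LD; estimation noise is
  blockwise-correlated with the reported SEs
  (`sqrt(σ²_resid/(n·var(g)))` for quantitative traits,
  `sqrt(1/(var(g)·N·φ(1−φ)))` for case fraction φ).  Directional
  pleiotropy adds a positive direct outcome effect, oriented to the
  exposure-increasing allele, to a configurable fraction of
  instruments.  Palindromic variants are created by relabelling
  alleles post hoc with reported EAF near 0.5 (drawn U[0.40, 0.60], so
  both sides of the 0.42 rule occur); the underlying effects — hence
  the truth — are unchanged, which means reported EAF for those
  variants is deliberately decoupled from the panel frequency.
* **Seeding**: one master seed expands to named per-component streams
  through `numpy.random.SeedSequence` with fixed entropy tags; the
  exposure-side streams can be pinned (`exposure_seed`) so several
  metabolites share one exposure GWAS.  Every generator is a pure
  function of (arguments, seed).

What the generator does **not** emulate: realistic human LD maps and
allele-frequency spectra, sample overlap between GWAS, imputation
uncertainty, sex-stratified effects, winner's-curse selection of the
published instruments, or population stratification.  Passing tests
therefore demonstrate the statistical machinery under the stated
model, not robustness to those real-data complications.

## Reference simulation sizes

Calibration and recovery runs use sizes chosen once for adequate
power at desk scale: null calibration at n = 20,000 per GWAS, 50
instruments, 500 replicates; effect recovery (β = 0.3) at n = 50,000,
200 replicates; colocalisation calibration on two 25-variant blocks
(panel n = 2,000, within-block r = 0.8, causal |z| = 10), 100
replicates per mode; mediation recovery at n = 100,000 per sample
(the scale of consortium cancer GWAS) with the true proportion set by
scaling the mediator→outcome path at a fixed total effect of 0.25.
For null calibration the reported type-I error is that of the
fixed-effects IVW z-test, which is exactly standard normal in this
design; the random-effects variant's floored overdispersion makes it
deliberately conservative (empirically ≈3–4% at α = 0.05).

## Numerical choices and degenerate inputs

Posterior normalisation in colocalisation tolerates −∞ hypothesis
terms (e.g. H3 in a one-variant region).  The mode estimator returns
the common value when all ratios coincide (zero spread); zero
`bandwidth_factor` is rejected.  `harmonise` treats duplicated variant
ids as exclusions, not failures.  Clumping tolerates variants absent
from the panel (logged drop).  Overlap filtering resolves sample-size
ties by removing from the exposure set, whose instrument count is
larger in this design, minimising mediator power loss.  The Stage-2
Bonferroni denominator is configurable (`global` across all
metabolite–cancer tests, the default, or `per_outcome`).

## Known limitations

The difference-method SE ignores the covariance between total and
direct estimates (documented above).  Conditional F uses the
identity/estimated phenotypic correlation rather than individual-level
covariances.  Heterogeneity-robust MVMR point estimation (Q-minimising
variants with bootstrap CIs) is not implemented; the MVMR-IVW fit plus
its diagnostics routes weak/pleiotropic designs to the product method
instead.  Colocalisation assumes at most one causal variant per trait
per region; multi-signal regions need conditional or SuSiE-style
extensions out of scope here.
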