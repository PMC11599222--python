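# Methods

## Setting and assumptions

All computations operate on GWAS summary statistics: for each SNP and trait, a
per-allele effect estimate (log-odds for binary traits, SD units for
continuous ones), its standard error, the effect-allele frequency, a p-value
and the study sample size. Two-sample MR assumes the SNP–exposure and
SNP–outcome associations come from non-overlapping (or approximately
non-overlapping) samples of the same ancestry, and the instrumental-variable
assumptions: each instrument is associated with the exposure, independent of
confounders, and affects the outcome only through the exposure (no horizontal
pleiotropy — relaxed differently by each sensitivity estimator).

## Harmonization

Effects are keyed on rsid and aligned to the exposure study's effect allele.
Identical allele pairs pass through; swapped pairs negate the outcome beta
(and reflect the allele frequency); strand flips are resolved by complementing
the outcome alleles before comparison. Palindromic variants (A/T, C/G) are
excluded by default because their strand cannot be inferred from the allele
pair — this mirrors standard practice and is configurable. Every input SNP
ends either in the retained set or in an exclusion log with a reason
(`palindromic`, `allele_mismatch`, `missing_in_outcome`), so harmonization is
an accounting-complete operation.

## Instrument selection

Defaults: genome-wide significance p < 5×10⁻⁸ (strict inequality), minor
allele frequency min(eaf, 1−eaf) ≥ 0.3, pairwise r² < 0.01 within a 1,000 kb
window. The package does not ship an LD reference panel: callers either
supply a pairwise r² matrix (greedy clumping then keeps the smallest-p member
of each correlated group; window locality is assumed encoded in the matrix) or
pass pre-clumped instruments, in which case a warning notes the assumption.
The MAF ≥ 0.3 commonality filter is unusually strict by field standards; it is
applied at instrument selection and is configurable, since sources differ on
whether such filters target all instruments or only palindrome resolution.

Instrument strength: per-SNP R² = 2·MAF·(1−MAF)·β²/(SE²·N) and
F = ((N−K−1)/K)·R²/(1−R²). The strength report exposes two readings:
`f_mean_per_snp` (K=1 applied to the mean per-SNP R² — the mean single-SNP F,
the quantity conventionally tabulated next to per-study instrument counts,
e.g. F ≈ 19.9 for N=1,207,228 and R̄²=1.65×10⁻⁵) and `f_joint` (K=k on the
summed R², the joint strength of the whole set). F < 10 raises a
weak-instrument flag.

## Univariable estimators

- **IVW**: β̂ = Σwⱼβ̂Xⱼβ̂Yⱼ / Σwⱼβ̂Xⱼ², wⱼ = 1/σYⱼ²; fixed-effect SE
  (Σwⱼβ̂Xⱼ²)^−1/2. The random-effects flavor is *multiplicative*: the SE is
  inflated by √max(1, Q/(J−1)), never deflated, so the fixed-effect SE is a
  lower bound. A single instrument degrades to the Wald ratio with a warning.
- **MR-Egger**: weighted regression with intercept after orienting all
  β̂X ≥ 0. Slope = causal effect under InSIDE; intercept = average directional
  pleiotropy. Both SEs carry the same √max(1, Q/(J−2)) inflation.
- **Weighted median**: Wald ratios weighted by (β̂Xⱼ/σYⱼ)² (first-order
  inverse variance of the ratio, exposure noise ignored at the weighting
  stage); the estimate linearly interpolates the weighted empirical CDF at
  probability 0.5. Consistent when ≥50% of weight is on valid instruments.
- **Modes**: normal-kernel density over the ratios, bandwidth
  0.9·min(SD, MAD)·J^(−1/5) scaled by a user factor (default 1), mode taken
  as the argmax over a 512-point grid spanning the ratio range ±3 bandwidths;
  the weighted variant uses full delta-method ratio variances
  σY²/βX² + βY²σX²/βX⁴. Degenerate zero-spread inputs return the common
  ratio; zero-β̂X SNPs are excluded with a warning (undefined ratio).
- Median and mode SEs come from a parametric bootstrap (β̂X, β̂Y resampled from
  their normal sampling distributions; default 1,000 replicates, caller-fixed
  seed).

All confidence intervals are β ± 1.96·SE and p-values two-sided normal — a
deliberate, uniform convention matching the symmetric intervals such analyses
report; no t-corrections are applied.

**Cochran's Q** uses the fitted IVW slope (df = J−1) or Egger line (df = J−2)
with the same 1/σY² weights and a chi-square upper-tail p-value.

**MR-PRESSO**: for each SNP the expected outcome effect is the leave-one-out
IVW prediction; the observed weighted residual sum of squares is compared to a
parametric null in which β̂X* ~ N(β̂X, σX) and β̂Y* ~ N(β̂₋ⱼβ̂Xⱼ, σY) (default
1,000 draws). The global p is the empirical exceedance probability; per-SNP
empirical p-values are Bonferroni-adjusted across instruments and SNPs below
α = 0.05 are removed before IVW re-estimation. The downstream distortion test
is not implemented (removal + reanalysis is the supported workflow). With
1,000 simulations the smallest attainable per-SNP p is 1/1001, so Bonferroni
detection is possible for instrument sets up to ~50 SNPs at α = 0.05.

**Multiple testing**: Benjamini–Hochberg step-up adjustment (delegated to
statsmodels behind `bh_fdr`), applied across the family of all IVW tests in a
pipeline run (the family is the natural unit here; it is configurable in
spirit by running pipelines separately).

**Directional consistency** is reported as a flag — true when every non-IVW
estimate shares the IVW sign (zero counts as consistent) — not enforced as an
exclusion, since it is a reliability screen rather than a filter.

## Multivariable MR and mediation

The MVMR design takes the union of each exposure's instruments, aligns every
study to a common effect allele per SNP (reference = the contributing exposure
with the smallest p), and drops SNPs missing from any study. The fit is WLS of
β̂Y on the J×E exposure-beta matrix without intercept, weights 1/σY²;
coefficient SEs come from (XᵀWX)⁻¹ with √max(1, Q/(J−E)) random-effects
inflation. Rank-deficient designs fail with the collinear exposure pair named.

Mediation (log-odds scale): product method indirect = a·b with delta-method SE
√(a²se_b² + b²se_a²); difference method indirect = c − c′ with SE
√(se_c² + se_c′²) under an independence approximation (c and c′ share outcome
data, so this SE is approximate — a documented limitation). Proportion
mediated = indirect/total. Proportion CIs default to a parametric bootstrap
(10,000 draws, a/b/c/c′ resampled as independent normals, percentile
interval) because first-order delta propagation is a poor approximation for
ratios whose denominator CI approaches zero; the delta alternative is
provided. The b entering the product method is the *unadjusted* univariable
mediator→outcome estimate by default (mode `unadjusted`), with the MVMR-
adjusted b available as mode `adjusted` — the two differ whenever mediators
are correlated or the mediator's instruments overlap the exposure's.

The pipeline replicates the screening workflow: mediators whose
exposure→mediator or mediator→outcome IVW fails BH-FDR at α = 0.05 are
excluded from the multivariable and mediation stages; MR-PRESSO is triggered
for any univariable analysis whose IVW Q test has p < 0.05.

## Synthetic data

The generator emulates summary-level GWAS for an exposure, M mediators and an
outcome under the path model: mediator_i true effect = a_i·(exposure effect) +
own instrument block; outcome true effect = c_direct·(exposure effect) +
Σ b_i·(mediator effect) + pleiotropy offset; total effect
c = c_direct + Σ aᵢbᵢ holds exactly by construction. Observed betas add normal
noise with SE = 1/√(2·MAF·(1−MAF)·N); MAFs are uniform on (0.05, 0.5); alleles
are drawn from the eight non-palindromic ordered pairs so harmonization
attrition is zero by construction; binary-trait effects are generated directly
on the log-odds scale (no liability-threshold model — the analysis operates at
the summary level throughout). SNPs are independent (LD identity), so
clumping assumptions are trivially satisfied. Output is bit-reproducible for
a fixed seed.

Pleiotropy injection on the exposure instruments: `balanced` draws mean-zero
normal offsets (SD = magnitude); `directional` adds a constant offset on the
exposure-increasing allele, i.e. the offset carries sign(βX). The latter
convention matters: with random instrument sign-coding a sign-agnostic offset
would average to zero after Egger's βX ≥ 0 orientation, and no intercept
method could recover it.

Instrument effects are drawn as |z|·SE with z uniform on a configurable range,
default (8, 15) — comfortably genome-wide significant, per-SNP F ≈ 64–225.
Two preset scenarios:

- `study_scale_scenario()`: the scale of the motivating insomnia→MI study —
  429/77/34/60 instruments, sample sizes 1.21M/1.23M/0.94M/0.81M/0.40M, path
  coefficients a=(−0.626, −0.051, 0.264), b=(−0.317, 0, 0.391) for smoking,
  alcohol (a deliberately null mediator exercising the exclusion rule) and
  BMI, with c_direct set so the implied total is exactly 0.674; z range
  (5.6, 9.0) approximating the modest instrument strength of the real study.
  Intended for end-to-end structural smoke tests, not unbiased recovery: at
  that strength, and with the exposure's strong effect on smoking putting
  exposure SNPs into the smoking instrument set, the unadjusted product-method
  b is visibly confounded — the same reason real product- and
  difference-method decompositions disagree.
- `validation_scenario()`: 100+60 instruments, N=100,000 everywhere, z range
  (40, 70) (per-SNP F ≈ 1,600–4,900). This is the estimator-validation
  regime: weak-instrument regression dilution in summary-data MR is of
  relative order 1/F̄, and at F̄ ≈ 3,100 it sits an order of magnitude below
  the Monte-Carlo resolution of a 500-replicate recovery study, so recovery
  tests isolate estimator correctness from the separate, well-understood
  attenuation phenomenon.

What passing recovery tests therefore show: the estimators are correctly
implemented and unbiased when their assumptions hold. What they do not show:
performance under LD, sample overlap, winner's-curse instrument selection,
weak instruments, or liability-scale binary traits — none of which the
generator models.

## Numerical and design choices

- Problem sizes in the test suite: 500 replicates for recovery/size studies,
  100 replicates (1,000 null simulations each) for outlier-detection power,
  10–60 replicates for directional-recovery spot checks; bootstraps are
  trimmed to 50–500 replicates inside tests. These keep the full suite under
  a minute apart from the recovery study (~10 s) while leaving Monte-Carlo
  margins explicit in each assertion.
- Ties in clumping are broken by input order after the stable smallest-p sort.
- `snp_r2` clips at 1−ε with a warning; `f_statistic` requires N > K+1.
- Zero total effect is a hard error in mediation (proportion undefined);
  a = b = 0 falls back to the exact product-normal SE term se_a·se_b.
- Degenerate inputs: all-zero exposure betas (IVW), < 3 SNPs (Egger/median/
  mode), < 4 SNPs (MR-PRESSO), rank-deficient MVMR designs and ≤ E instruments
  all raise typed errors that the CLI maps to distinct exit codes
  (2 config, 3 data, 4 identification).

## Known limitations

- The difference-method SE assumes c and c′ independent; they are not, and
  the bootstrap proportion CI inherits the same approximation.
- No proxy-SNP search: instruments missing from the outcome study are
  discarded, never replaced.
- No Steiger filtering, leave-one-out analysis, contamination-mixture or
  profile-likelihood estimators; no MVMR-Egger/median; no conditional
  F-statistics for MVMR instrument strength.
- The generator's independence and strong-instrument idealizations mean
  synthetic benchmarks bound implementation error, not real-data error.
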