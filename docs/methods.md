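# Methods

## The estimation problem

Two-sample summary-data MR treats J approximately independent SNPs as
instruments for an exposure X. With per-allele SNP-exposure effects γ_j
(SE σ_γj, sample 1) and SNP-outcome effects Γ_j (SE σ_Γj, sample 2), a
valid instrument satisfies Γ_j = β γ_j, and β is the causal effect of X on
Y. All estimators here operate on a `HarmonizedSet`: SNPs matched by rsID
with both associations expressed per copy of the same effect allele, and
(by default) oriented so γ_j ≥ 0 — the "toward increasing exposure"
convention.

Harmonization resolves swapped alleles (flip the outcome beta, complement
its frequency) and strand flips (A↔T/C↔G relabelling, attempted only for
non-palindromic SNPs). Palindromic SNPs (A/T, C/G) are aligned by effect
allele frequency, and dropped as ambiguous when either frequency lies in
[0.5 − w, 0.5 + w] or is missing. The half-width w defaults to 0.08: the
conventional choice; the underlying rule ("remove palindromic SNPs with
intermediate frequency") does not itself fix a width.

## Estimators

**IVW.** Weighted regression of Γ on γ through the origin with weights
w_j = 1/σ²_Γj: β̂ = Σw γ Γ / Σw γ², fixed-effect SE (Σw γ²)^(−1/2). The
primary model is multiplicative random effects: the SE is inflated by
√max(1, Q/(J−1)) where Q is Cochran's statistic. The floor at 1 means
random effects never claim more precision than fixed effects. Inference is
normal-theory.

**MR-Egger.** The same regression with an intercept, fitted after the
γ ≥ 0 orientation (flipping a SNP flips both betas, so the intercept is
only identified relative to an orientation). The intercept estimates mean
directional pleiotropy under InSIDE (pleiotropic effects independent of
instrument strength). SEs are inflated by √max(1, Q′/(J−2)); inference
uses the t distribution on J−2 df because normal-theory intercept tests
are anticonservative at small J.

**Rücker model selection.** Q − Q′ (the heterogeneity absorbed by the
intercept) is referred to χ²₁; MR-Egger becomes the primary method iff
that test rejects at 0.05 *and* the intercept differs from zero at 0.1.
Q′ ≤ Q is enforced exactly (nested weighted least squares cannot increase
the residual sum; floating-point excursions are clipped).

*Power of the switch.* Under planted directional pleiotropy the same
pleiotropy that creates the intercept also inflates Q′, so the intercept
t-statistic is bounded roughly independently of the pleiotropy magnitude
and grows only as √J. The model-selection experiment therefore uses a
kidney-instrument-sized J = 100 (the motivating study's kidney instruments
had 133 and 45 SNPs); at J = 50 the switch has little power even under
strong directional pleiotropy.

**Weighted median.** Wald ratios ordered ascending with normalized
inverse-variance weights; the estimate interpolates at cumulative weight
1/2 using midpoints p_j = (S_j − w_j/2)/ΣW. SE by parametric bootstrap
(γ*, Γ* resampled from normals at their SEs; default n_boot = 1000,
seeded). Consistent when valid instruments carry > 50% of weight, but with
one-sided pleiotropy it retains a finite-sample bias proportional to the
Wald-ratio noise (the 50%-weight point sits in the upper tail of the valid
cluster); the robustness experiment accordingly compares biases on the
scale of the estimator's Monte-Carlo SD, on which the weighted median is
unbiased to within 2 SDs while IVW is not.

**MR-PRESSO.** For each SNP the expected outcome effect is γ_j β̂(−j)
(leave-one-out IVW); RSS_obs = Σ w_j (Γ_j − γ_j β̂(−j))² is referred to a
parametric-simulation null (Γ*_j ~ N(γ_j β̂(−j), σ_Γj), γ*_j ~ N(γ_j,
σ_γj), n_sim draws, leave-one-out recomputed per draw). Global and
per-SNP p-values are empirical with the (1+k)/(1+n_sim) estimator, so they
are never exactly zero; per-SNP outlier p-values are Bonferroni-adjusted
by J. Consequence: the smallest achievable adjusted outlier p is
J/(n_sim+1), so n_sim must comfortably exceed J/α for the outlier test to
have any power — the default n_sim = 1000 suffices for instruments of a
few dozen SNPs. The corrected estimate is IVW on non-flagged SNPs; the
distortion test compares the raw-vs-corrected shift against removal of
random subsets of the outlier count (two-sided empirical p).

**Steiger.** Per-SNP variance explained r² = t²/(t² + n − 2) with
t = beta/SE, per trait; direction is "valid" when r²_exp > r²_out. The
z test transforms the implied |correlations| with Fisher's atanh and
standardizes by √(1/(n_exp−3) + 1/(n_out−3)). Filtering defaults to the
point-estimate rule with the p-value reported (a significance mode is
available). For binary outcomes the same t-based r² on the reported N is
used — a documented approximation. Aggregate directionality sums per-SNP
r² and applies the same z test at the mean sample sizes.

**Multivariable MR and mediation.** Γ regressed on (γ, δ) without
intercept, weights 1/σ²_Γj; SEs from the weighted normal equations
inflated by √max(1, RSS_w/(J−2)). An all-zero mediator column reduces
exactly to univariable IVW; genuinely collinear columns (condition number
> 1e12) raise. The difference method sets indirect = total − direct with
SE √(σ²_total + σ²_direct) under an independence approximation — the two
estimates share the outcome sample, so this is approximate; a parametric
bootstrap for the proportion CI is provided. The proportion mediated is
undefined when |total| is numerically zero.

## Instruments

Clumping is greedy: sort qualifying SNPs (p < 5×10⁻⁸ by default) by
ascending p, ties broken by (chrom, pos, snp) for row-order-independent
determinism; keep the best, discard same-chromosome SNPs within 500 kb at
r² ≥ 0.1. LD is user-supplied as sparse pairs; a missing pair is treated
as r² = 0 (sparse inputs are the norm). Exclusion lists remove listed SNPs
and anything at r² > 0.8 to them. Dual-marker refinement keeps SNPs whose
association with a second marker of the same physiology is Bonferroni
significant at 0.05/n_index and (by default) directionally consistent —
concordant for a concordant marker such as cystatin-based eGFR, discordant
for an inverse marker such as blood urea nitrogen. Weak-instrument flag at
mean F < 10 (conventional).

## Power

Closed form: power = Φ(−z_{1−α/2} + ncp) + Φ(−z_{1−α/2} − ncp) with
ncp = |b|√(nR²) (continuous, standardized traits) or
|log OR|·√(nR²K(1−K)) (binary, case fraction K). The binary noncentrality
is the score-test form; both formulas are pinned by a Monte-Carlo oracle
(simulate summary statistics, run IVW, count rejections) rather than by
transcribed constants. The oracle defaults to the closed form's own
assumptions — instrument effects known (NOME) and the fixed-effect z-test —
and exposes switches to quantify the extra power loss from finite exposure
samples (regression dilution) and the random-effects SE floor; both losses
are a few percentage points at moderate power.

## Synthetic data

Generative model: X = Σγ_j G_j + qU + e_x;
Y = βX + Σα_j G_j + rU + e_y, with G_j ~ Binomial(2, f_j), U a shared
standardized confounder (q = r = 0.3 by default; harmless in two-sample
designs with disjoint samples, present for realism), and both traits
scaled to unit variance (the generator refuses configurations where the
structural terms would exceed 95% of the outcome variance). Defaults
describe the emulated study conditions: J = 50 SNPs, MAF uniform on
(0.05, 0.5), 50,000 per sample, instrument R² = 4% — the upper end of what
the epigenetic-clock instruments explain — and no pleiotropy.

Pleiotropy: a fraction `prop_invalid` of SNPs receives
α_j ~ N(mean_alpha, sd_alpha²) *on the exposure-increasing allele
orientation* (α multiplied by sign(γ_j)). This matters: with sign-symmetric
γ, planting α in the raw allele frame would let the γ ≥ 0 orientation flip
half the α's and turn nominally directional pleiotropy into balanced
pleiotropy. The `correlated` flag instead scales α with γ to violate
InSIDE for stress tests.

Two modes. `asymptotic` draws γ̂, Γ̂ from their sampling distributions
(SE ≈ √((1 − b²h)/(nh)), h = 2f(1−f); binary outcomes use the log-odds
SE 1/√(nK(1−K)h)) — this is what the large replicate experiments use.
`individual` simulates the two participant pools (disjoint up to an
optional overlap fraction, to study overlap bias) and runs per-SNP
linear or logistic regressions; the logistic intercept is solved
numerically for the target prevalence. The tests verify the two modes
agree in their first two moments at matched parameters.

Mediation systems add a mediator M with its own J_med instrument SNPs:
M = b_xm X + Σκ_j G_j + e_m, Y = b_direct X + b_my M + e_y, with b_my
chosen so the mediated fraction of the total effect equals the configured
value.

The individual-level cohort generator emulates a biobank: dosages
(optionally in equicorrelated LD blocks via a Gaussian copula), age
uniform on 50–65, clinical covariates at plausible prevalences, 10
synthetic ancestry PCs, and biomarkers constructed by *inverting* the 2012
combined creatinine–cystatin C estimating equation so that derived eGFR
reproduces a planted linear model (baseline median 92 ml/min/1.73 m²,
log-scale SD 0.22 → CKD prevalence ≈ 3%) exactly; a random split
apportions the eGFR deficit between the two biomarkers. What it does not
emulate: realistic genome-wide LD, assay noise in the biomarkers,
population stratification actually correlated with genotype, or
missingness. Passing tests therefore demonstrate correctness of the
estimators and plumbing under the stated model, not robustness to those
real-data features.

## Phenotypes and scores

The eGFR equation is the 2012 combined creatinine–cystatin form with
sex-specific knots (κ = 0.7/0.9, exponents −0.248/−0.207) and the 0.969
female multiplier; the race coefficient is not applied by default
(configurable), matching a White-British-style cohort. CKD is strictly
eGFR < 60. "Standard normal transformed" allele scores are implemented as
z-scores (the linear-score convention); a rank-based inverse-normal
transform is available as an option. Binary-outcome associations are
reported as odds ratios: the fitted model is logistic regression, so odds
ratios are what it produces, whatever label a report table may prefer.

## Pipeline conventions

Per exposure-outcome pair: clump → exclusion list → harmonize → Steiger
filter → Rücker selection → weighted median and MR-PRESSO → strength and
directionality diagnostics → unit scaling (e.g. ×5 for per-5-year effects;
binary outcomes exponentiated to the odds scale after scaling; p-values
unchanged). FDR is Benjamini–Hochberg within a configurable family,
defaulting to the exposures of one outcome within one direction (pooling
across outcomes/directions is a config switch). Failures are isolated per
pair. All randomness descends from one master seed via spawned
sequences; floats are rounded to 10 decimals before writing so identical
config + seed gives byte-identical TSV/JSON.

## Experiment sizes

The replicate experiments run at the stated study conditions — J = 50,
n = 50,000 per sample, 1,000 replicates for calibration/recovery, 200 for
the selection/robustness/directionality rates, 50 for outlier handling,
2,000 per cell for the 27-cell power grid — using the asymptotic mode, so
the whole acceptance battery completes in seconds on one CPU.

## Known limitations

- Wald-ratio SEs are first-order delta method (γ uncertainty ignored).
- The indirect-effect SE ignores the total/direct covariance.
- Correlated-instrument (generalized) IVW, mode-based and
  robust-profile-likelihood estimators are out of scope.
- Steiger r² for binary traits reuses the continuous t-based formula.
- No liftover, proxy-SNP lookup, or reference-panel LD computation:
  positions, LD and exclusion lists are inputs.
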