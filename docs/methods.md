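# Methods

## Model and assumptions

Two-sample summary-data MR treats each instrument SNP j as a natural
experiment. With exposure association β_Xj (SE σ_Xj) and outcome
association β_Yj (SE σ_Yj), both on the log-odds scale for binary
traits, the structural model is β_Yj = θ·β_Xj + α_j, where θ is the
causal effect and α_j the horizontal-pleiotropy shift (zero for a
valid instrument). The three instrumental-variable conditions are:
relevance (β_Xj ≠ 0, enforced by the significance filter), independence
from confounders (approximated by the catalog screen), and exclusion
restriction (α_j = 0, probed by the sensitivity toolkit rather than
assumed).

Estimators and the exact formulas used:

* **Wald ratio** θ̂_j = β_Yj/β_Xj; first-order SE σ_Yj/|β_Xj| by
  default (the convention of the standard MR software ecosystem, which
  keeps IVW identical to weighted regression through the origin with
  outcome-variance weights); the second-order delta-method SE
  √(σ_Yj²/β_Xj² + β_Yj²σ_Xj²/β_Xj⁴) is available by flag and is never
  smaller.
* **IVW**: θ̂ = Σw_jθ̂_j/Σw_j, w_j = se(θ̂_j)⁻². Fixed-effect SE
  (Σw_j)^(−1/2); the multiplicative random-effects model scales the SE
  by max(1, √(Q/(k−1))) and never changes the point estimate. P-values
  use the normal reference.
* **MR-Egger**: pairs are oriented so β_Xj ≥ 0 (joint sign flips leave
  every ratio invariant), then β_Y is regressed on β_X with a free
  intercept and weights 1/σ_Yj². Both SEs carry a multiplicative
  overdispersion factor bounded below at 1 — computed from the
  unit-variance covariance (XᵀWX)⁻¹ scaled by max(1, σ̂), which stays
  defined even for an exact-line fit — and p-values use t(k−2). The
  intercept estimates the mean directional pleiotropy.
* **Weighted median**: ratios sorted ascending; with normalized weights
  p_j, the estimate is the value where S_j = Σ_{i≤j} p_i − p_j/2
  crosses 1/2, linearly interpolated between the bracketing ratios.
  Because the interpolation is local, duplicating a SNP while halving
  its weight is exactly neutral unless the duplicate brackets the
  crossing interval. SE by seeded parametric bootstrap (betas redrawn
  from Normal(β̂, σ), default 1000 draws).
* **Mode estimators**: normal-kernel density of the ratios (weights
  uniform or inverse-variance), bandwidth h = φ·0.9·min(sd,
  MAD·1.4826)·k^(−1/5), maximised on a 10,000-point grid spanning
  [min−h, max+h]; grid error is far below the bootstrap SE at these
  bandwidths. All identical ratios return the common value directly.
* **OR scale**: OR = exp(θ̂), 95% CI exp(θ̂ ∓ 1.959964·se), two-sided
  normal p.

Sensitivity statistics: Cochran's Q = Σw_j(θ̂_j − θ̂_IVW)² with
p from χ²(k−1) and I² = max(0, (Q−df)/Q)·100; leave-one-out re-runs
fixed-effect IVW k times; MR-PRESSO computes RSS_obs =
Σ_j w_j(β_Yj − θ̂₍₋ⱼ₎β_Xj)² with leave-one-out IVW expectations and
w_j = 1/σ_Yj² (an exposure-variance term can be added by flag), a
global p from a parametric bootstrap under the no-pleiotropy model
(empirical p with the +1 correction), per-SNP outlier p-values against
each residual's simulated distribution with Bonferroni (×k)
adjustment, and — only when outliers exist — a distortion p comparing
the outlier-corrected estimate against random removals of the same
count. With the empirical-p construction, n_sim must exceed
k/0.05 for any outlier to be flaggable after Bonferroni; the default
n_sim = 1000 satisfies this for k ≤ 50.

## Selection and harmonization rules

Selection: p < 5e-8 (forward) or 5e-6 (reverse, the usual relaxation
for a small exposure GWAS); greedy clumping in deterministic order
(ascending p, then chromosome, position, rsid) with a SNP dropped when
an already-kept SNP on the same chromosome lies within ±10,000 kb and
has r² > 0.001; SNPs absent from the LD reference are kept as isolated
and logged, since clumping against an external panel cannot resolve
them. The confounder screen removes a SNP when it, or any proxy with
r² > 0.80, associates with a listed confounder trait at p < 5e-8.
Every stage logs (n_in, n_out, dropped rsids), and n_in = n_out +
|dropped| is asserted throughout.

Harmonization: same-orientation outcome records are taken as-is;
swapped alleles flip the outcome beta's sign and complement its EAF;
incompatible allele sets are excluded. Palindromic SNPs (A/T, C/G)
cannot be oriented from alleles alone; under the default
`drop_intermediate` mode they are excluded when either study's EAF
falls in (0.42, 0.58) — or when the outcome EAF is missing — and
otherwise oriented by requiring the same allele to be minor in both
studies. A `drop_all` mode removes every palindrome; published counts
are often consistent with either convention, so both are provided and
neither is asserted as *the* historical behaviour.

Instrument strength: R²_j = 2·MAF_j(1−MAF_j)(β_j/SD)² with MAF =
min(EAF, 1−EAF) and trait SD defaulting to 1 (log-odds scale);
total R² sums per-SNP values (justified post-clumping);
F = ((N−k−1)/k)·R²/(1−R²), with F > 10 (strict) called strong. The
summed-R² approximation can exceed 1 for very strong simulated
effects, outside the F formula's domain; F is then reported as
undefined rather than extrapolated.

## Synthetic-data generator

`simulate_study` emulates the summary-level structure the analysis
consumes, not genotypes. Per instrument: MAF ~ Uniform(maf_range);
γ_j ~ Normal(0, gamma_sd) resampled until the *true* effect is
significant at the exposure sample size (selection on truth, so
observed effects carry no winner's-curse bias); effect alleles are
coded exposure-increasing (as in risk-allele tables), which is what
makes mu_alpha ≠ 0 "directional" in the Egger sense; α_j ~
Normal(mu_alpha, sd_alpha) for the invalid fraction;
se = 1/√(2N·MAF(1−MAF)) on the unit-variance scale; observed betas add
Normal(0, se) noise; p-values are two-sided Wald tests floored at
1e-300. LD blocks replicate an index SNP's observed signal scaled by
r = √r², with the same SE, so tags are strictly less significant and
clumping resolves blocks deterministically. Palindromic instruments
receive A/T or C/G alleles with EAF ~ Uniform(0.45, 0.55) so the
intermediate-frequency rule fires. Confounder-catalog rows and
missing-outcome SNPs are planted verbatim. Identical configs are
bit-identical; different seeds differ.

What the generator does **not** model: realistic allele-frequency
spectra and effect-size architecture, case/control imbalance (N is an
effective sample size), LD computed from genotypes, sample overlap
between the two GWAS, and population stratification. Passing tests
therefore demonstrate the estimators' statistical properties under the
stated summary-level model, not robustness to those real-data
complications.

Study-shaped scenarios (`ibd_rosacea_scenario`): forward — k = 44,
N_exp = 86,640, N_out = 212,334, θ = log 1.1291, gamma_sd = 0.15
(typical immune-disease lead-SNP log-odds effects); reverse — k = 12
at the 5e-6 threshold, θ = 0, gamma_sd = 0.02, the weakest effects the
selection threshold admits. A genuinely weak instrument set (F ≈ 5)
cannot coexist with truth-level significance at p < 5e-6 and
N = 212,334: any true effect reaching |z| ≥ 4.56 contributes
R² ≥ z²/N, bounding F ≥ z² ≈ 21 regardless of MAF. The reverse
scenario therefore represents "weak relative to the forward direction"
rather than a literal F near 5.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| p_forward / p_reverse | 5e-8 / 5e-6 | instrument significance thresholds |
| clump_r2 / clump_window_kb | 0.001 / 10,000 | LD-independence thresholds |
| confounder_p / proxy_r2 | 5e-8 / 0.80 | confounder-screen thresholds |
| eaf_window | (0.42, 0.58) | intermediate-EAF band for palindromes |
| n_boot | 1000 | parametric-bootstrap draws for median/mode SEs |
| presso n_sim | 1000 | MR-PRESSO bootstrap replicates |
| phi | 1.0 | mode-estimator bandwidth multiplier |
| seed | 20230909 | default seed for every stochastic component |
| alpha | 0.05 | verdict significance level |

The pipeline's causal verdict uses IVW as the primary method (the
other four are concordance checks), with the fixed-effect model when
the heterogeneity p ≥ 0.05 and multiplicative random effects
otherwise; both SEs are derivable from the stored Q.

## Numerical and design choices

* Clumping ties break deterministically (p, chromosome, position,
  rsid), making output invariant to input row order.
* The confounder-screen threshold is 5e-8 and configurable.
* Egger p-values use t(k−2); everything else uses the normal reference.
* Bootstrap and simulation seeds are explicit everywhere; default
  20230909.
* The empirical-p "+1" convention keeps all bootstrap p-values in
  (0, 1].
* Reported p-values are floored at the smallest positive double.
* Degenerate inputs: one instrument → single-SNP Wald fallback in the
  pipeline (estimators themselves refuse below their minimum k);
  zero-variance exposure effects → explicit degenerate-regressor
  error; identical ratios → Q = 0, I² = 0, mode/median return the
  common value.
* Test and acceptance problem sizes: oracle equivalences at 100 random
  sets; coverage and type-I error at 300–500 replicates of the k = 44
  scenario; MR-PRESSO calibration at 200 replicates × 200 simulations
  and detection at 50–100 replicates × 600–1000 simulations — sizes at
  which the binomial noise of each rate sits well inside its stated
  tolerance band.

## Known limitations

* First-order Wald SEs understate uncertainty when exposure effects
  are weak (NOME violation); no SIMEX correction is provided.
* The weighted median's consistency argument needs pleiotropic ratio
  shifts comparable to per-SNP noise or invalid weight < 50%; under
  cleanly separated directional contamination its bias-to-SE ratio
  grows like √k and no reweighting can rescue it — that regime is what
  MR-PRESSO outlier removal is for.
* MR-PRESSO p-values are bootstrap-based and only reproducible given
  the seed; published values from other software match
  distributionally, not digit-for-digit.
* The distortion test is skipped (None) when no outliers are found.
* No MR-RAPS, Steiger filtering, multivariable MR, or Radial-MR.
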