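# Methods

## Scope and data model

The package operates entirely on GWAS summary statistics: per-variant
marginal association estimates (beta, SE, p, allele pair, effect-allele
frequency, sample size) for an exposure, candidate mediators and an
outcome, each from a separate (non-overlapping) study.  Effects for
continuous traits are in SD units; binary-trait effects enter as odds
ratios and are converted to log-odds on input — all mediation arithmetic
happens on additive scales, and ORs are re-exponentiated only in the
report layer.  Variant matching across tables is by rsID alone;
positions are carried for clump windows but no genome-build handling is
attempted, and proxy instruments are never searched.

## Instrument selection and harmonization

Instruments are variants associated with their trait at a configurable
significance threshold (default p < 5×10⁻⁸), pruned by greedy LD
clumping: scanning in order of ascending p (ties broken by rsID for
determinism), a variant is dropped if it is correlated at r² ≥ the
cutoff with an already-kept variant within the physical window.
Defaults are r² < 0.001 within 10,000 kb for the exposure and r² < 0.01
within 1,000 kb for mediators, both configurable per trait.  The package
does not bundle reference-panel LD; when no LD map is supplied all
significant variants are retained and an explicit independence-assumed
warning is logged.  The synthetic generator emits independent SNPs, so
clumping logic is exercised by tests with explicit r² fixtures.

Harmonization aligns every table to the exposure's effect allele:
swapped-allele records have beta negated and EAF mapped to 1−EAF;
strand-complement matches are accepted; palindromic (A/T, C/G) variants
are resolved by effect-allele frequency when both frequencies fall
outside the ambiguity window [0.42, 0.58], and dropped otherwise.  The
window is a design choice mirroring common MR practice — the original
workflow this reimplements does not state its palindrome policy, so no
claim is made of matching it; the window is configurable.  After
harmonization, instruments directly associated with the *outcome* at
genome-wide significance can be excluded (default on, per the source
workflow's exclusion-restriction guard).  Note this guard is
intentionally disabled in the simulation recovery studies: with the
strong simulated causal effect, many valid instruments are genuinely
outcome-associated *through the exposure*, and excluding them selects
for small exposure effects and biases the total-effect estimate — a
selection effect worth remembering when applying the rule to strongly
causal real traits.

## Estimators

* **IVW** — estimate Σwβ̂_Xβ̂_Y/Σwβ̂_X², w = 1/SE_Y²; fixed-effect SE
  (Σwβ̂_X²)^(−1/2); multiplicative random effects (default) inflate by
  max(1, √(Q/(J−1))).  p two-sided normal.
* **MR-Egger** — weighted regression with intercept after orienting each
  SNP to a non-negative exposure beta; SEs inflated by
  max(1, residual dispersion); slope and intercept tested against t with
  J−2 df, chosen for small-J behaviour of the intercept test.
* **Weighted median** — ratios ordered ascending, normalized
  inverse-variance weights, cumulative midpoints pₖ = (Sₖ − wₖ′/2)/S_J,
  linear interpolation at p = 0.5; SE by seeded parametric bootstrap
  (default 1000 replicates) redrawing both exposure and outcome betas.
* **MR-PRESSO** — observed weighted RSS about leave-one-out IVW
  predictions compared to a parametric simulated null (default 1000
  draws); per-SNP outlier p-values Bonferroni-corrected at 0.05/J;
  corrected fit = IVW without flagged SNPs; distortion p from random
  same-size removals.  One simplification relative to the original
  algorithm: observed leave-one-out slopes are reused across simulated
  draws instead of being re-estimated per draw, which is accurate when
  no single SNP dominates the fit and keeps the test O(n_sim·J).  Note
  the outlier test's minimum attainable p is 1/(n_sim+1); n_sim must
  exceed J/α for the Bonferroni threshold to be reachable.
* **MVMR** — weighted least squares of outcome betas on the J×K exposure
  beta matrix (no intercept; Egger variant adds one after orienting rows
  by the first exposure), dispersion floored at 1, rank checked by SVD
  with a 1e-10 relative tolerance so duplicated exposures raise a
  collinearity error.  Conditional F for exposure k is the weighted
  residual Q of its betas regressed on the co-exposures' betas, divided
  by J−K, with cross-trait sampling covariance taken as zero
  (two-sample, non-overlapping design) — an approximation, stated as
  such.  With one exposure it falls back to the marginal mean F.

Wald-ratio SEs are first-order (SE_Y/|β̂_X|) by default; the
second-order form adding exposure sampling error is available.

## Mediation decomposition

The two-step procedure estimates a (exposure→mediator, univariable IVW
on the exposure's instruments), b and c′ (MVMR of exposure plus
mediator(s) on the outcome), and c (univariable IVW).  Joint MVMR
instrument sets are the union of each trait's own selected instruments,
intersected with availability in every table; a mediator entering MVMR
needs ≥ 2 jointly-available instruments (configurable) — a
single-instrument mediator is excluded with a machine-readable reason.
The per-mediator indirect effect uses the product method a·b with the
Sobel SE and, optionally, a seeded Monte-Carlo percentile interval
(default 100,000 draws) that respects the product's skewness; the
combined-mediator indirect effect uses the difference method c − c′
only.  The difference-method SE √(σ_c² + σ_c′²) and the delta-method
proportion-mediated CI both assume independence between estimates that
in fact share instruments; both are flagged approximations, matching
what any summary-level workflow can do without instrument-level
covariances.  Proportions mediated are reported unclipped — values
outside [0, 1] are meaningful sign diagnostics, not errors — with a
sign-consistency flag.

Mediator screening retains a candidate iff the exposure associates with
it causally (IVW p below the screening level) and it associates with
the outcome (unadjusted, exposure-adjusted, or either, per
configuration), and it passes the joint-instrument minimum.

## Synthetic data generator

The generator emulates three non-overlapping GWAS under
X = Σγⱼgⱼ, M = aX + Σαⱼgⱼ, Y = c′X + bM + Σδⱼgⱼ, emitting marginal
effects plus normal noise with SE = 1/√(2·maf(1−maf)·N) for unit-SD
traits (binary outcomes: scaled by 1/√(prev(1−prev)) on the log-odds
scale — a linearized approximation that ignores non-collapsibility).
Reference conditions: J = 150 instruments, maf ∈ (0.1, 0.4),
|γ| ∈ (0.02, 0.10) with random signs, a = −0.3, b = 0.35, c′ = −0.5,
N = 5×10⁵ per study.  The mediator-specific effects αⱼ (SD 0.03 by
default) serve two roles: they are the mediator's own instruments —
without them the MVMR design matrix is exactly collinear and (b, c′) are
unidentified — and, viewed from the exposure's instruments, they are
balanced pleiotropy.  Directional outcome pleiotropy (nonzero-mean δ) is
applied on the exposure-increasing allele, the orientation in which
directional pleiotropy biases MR estimators; a zero-mean δ is balanced
and leaves the Egger intercept test at its nominal level.  SNPs are
independent (no LD), placed 20 Mb apart so clump windows never couple
them.  What the generator does *not* emulate: LD structure, sample
overlap, population stratification, winner's-curse selection into the
exposure GWAS, and binary-trait non-collapsibility — so passing recovery
tests demonstrate estimator correctness under the stated model, not
robustness to those real-data features.

Presets: `null` (a = b = c′ = 0), `strong-mediation` (reference
conditions), `directional-pleiotropy` (δ ~ N(0.01, 0.005)),
`weak-instruments` (|γ| ∈ (0.003, 0.007), mean F ≈ 5), `binary-outcome`
(prevalence 0.1).  Identical seeds give byte-identical files.

## Numerical and design choices

* WLS is solved by normal equations (K ≤ a handful; conditioning is a
  non-issue at these sizes) with an SVD rank guard.
* p-values are floored at 1e-300 to respect the (0,1] invariant.
* Clump ties in p break by rsID; all stochastic steps (median bootstrap,
  PRESSO, Monte-Carlo CIs) require seeds in the pipeline configuration,
  and the run manifest records every derived seed.
* Report tables round half-away-from-zero at 2 decimals for display;
  the JSON bundle retains full precision.
* Reverse-direction MR is a configuration-level role swap, not a code
  path.
* Problem sizes in the validation studies (200 decomposition replicates;
  500 Egger-calibration replicates at J = 50; 100 PRESSO replicates at
  J = 30, n_sim = 1000) were chosen to give Monte-Carlo SEs comfortably
  below the effects being checked while keeping the whole suite
  desk-scale.

## Known limitations

The bundled published-estimate example reproduces mediation arithmetic
from printed, rounded inputs; rows whose printed values reflect
unrounded internals (e.g. the FEV1/FVC proportions, where the printed
3.79 recomputes as ≈3.5 from 2-dp inputs) cannot be matched exactly and
are documented rather than forced.  Sample overlap between studies,
Steiger filtering, mode-based estimators and individual-level
(counterfactual) mediation are out of scope.
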