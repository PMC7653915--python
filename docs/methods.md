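# Methods

This note records the statistical model behind `summr`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that were genuinely open.

## Estimation model

All estimators operate on a harmonized set of k independent SNPs with
exposure associations (β̂_Xj, σ_Xj), outcome associations (β̂_Yj, σ_Yj)
and outcome-side weights w_j = σ_Yj⁻².  The outcome is binary throughout
the motivating design, so β_Y and every causal estimate are log odds
ratios per exposure unit (one SD of the exposure); `MRResult.odds_ratio()`
exponentiates estimate and CI, and refuses continuous outcomes.

**IVW.** Weighted least squares of β̂_Y on β̂_X through the origin.  The
effects model is *multiplicative random effects* by default: the
coefficient SE is scaled by σ = √max(1, Q/(k−p)) where Q is the weighted
residual sum of squares.  The floor at 1 means random effects can never
report more precision than fixed effects.  The fixed-effect switch sets
σ = 1.  The default follows the multivariable model's stated convention
(random effects) so single- and multi-exposure results are comparable.

**MR-Egger.** The same regression with a free intercept, after flipping
each SNP (β̂_X, β̂_Y jointly) so β̂_X ≥ 0.  The intercept estimates the
average directional pleiotropic effect on the exposure-increasing allele;
its Wald test is the pleiotropy test.  SE scaling uses Q/(k−2).

**Weighted median.** Wald ratios θ̂_j = β̂_Yj/β̂_Xj are ordered; weights
are first-order inverse ratio variances β̂_Xj²/σ_Yj²; the estimate
interpolates the ratio at standardized cumulative weight 0.5 using
p_j = (S_j − w_j/2)/S_k.  The SE is a parametric bootstrap (β̂_X, β̂_Y
redrawn from their SEs, B = 1000 by default, seeded).

**Weighted mode.** Gaussian-kernel weighted density of the Wald ratios
with bandwidth h = φ · 0.9 · min(SD, 1.4826·MAD) · k^(−1/5) (φ = 1 by
default), evaluated on a 512-point grid spanning the ratios ± 3h; the
estimate is the density argmax, ties resolving to the smallest value so
the result is deterministic.  SE by the same parametric bootstrap.  The
bootstrap CI of a kernel-mode is conservative: in our recovery
simulations its empirical 95% coverage is ≈ 0.99 while the estimate is
essentially unbiased.  This is a property of the method, not a defect of
the data; consumers should treat the mode as a sign/magnitude sanity
check, not a precision-weighted estimate.

**MVMR.** Weighted least squares of β̂_Y on the k×p exposure-beta matrix
with no intercept; each coefficient is a direct effect conditional on the
other exposures.  Rank deficiency raises an error naming the collinear
columns.  MVMR-Egger sign-orients all rows on a named reference exposure
(default: the first listed) before adding the intercept; the orientation
choice affects the intercept and is therefore explicit and logged.
Conditional (per-exposure) instrument-strength statistics are *not*
computed: the required covariances between SNP-exposure associations need
individual-level data when exposure samples overlap.

## Diagnostics

**Cochran Q** of β̂_Y around θ̂·β̂_X, df k−1 (k−2 for the Egger variant),
chi-square upper tail.

**MR-PRESSO.**  For each SNP the model is re-fitted leaving it out; the
observed statistic is the weighted residual sum of squares of each SNP
against its leave-one-out prediction.  The null distribution comes from
parametric simulation of both β̂_X and β̂_Y under the fitted model
(n_sim = 1000 by default), and p-values use the add-one rule, so the
smallest attainable p is 1/(n_sim+1) and the procedure is valid at any
n_sim.  Per-SNP outlier p-values compare each SNP's observed contribution
with its simulated contributions; outliers are flagged at p < 0.10.  The
multivariable case runs the identical leave-one-out scheme with the
MVMR-IVW fit as the engine — the natural generalization, labelled as
such.  Inputs are internally sorted by rsID so results are invariant to
row order at a fixed seed.  The optional distortion test is off by
default.  In the pipeline, *pruning* on the flagged outliers happens only
when the global test itself is significant (p < 0.05, configurable):
removing chance-flagged SNPs from a homogeneous set shrinks the
heterogeneity estimate and makes the re-fitted CI anti-conservative, which
we verified directly in null simulations.  The unconditional
`remove_outliers_and_rerun` operation remains available.

**Steiger.**  Per-SNP variance explained is approximated from summary
data as z²/(z²+n) and summed over instruments for each trait; the sums
are compared via Fisher-z transformed correlations with a two-sided
normal test.  For binary traits this is an observed-scale approximation
and is flagged as such in the result.

**Decision battery** (pipeline): (1) sign agreement across all four
single-variable estimators; (2) IVW p < α = 0.025 (two primary exposures,
no further correction); (3) no pleiotropy indication — MR-PRESSO global
p > 0.01 *and* Egger intercept p > 0.01; (4) Steiger p < 0.01 in the
assumed direction.  The headline estimate per analysis is outlier-pruned
IVW; unpruned results are always emitted alongside.

## Instruments and harmonization

Instruments are SNPs with p strictly below 5×10⁻⁸, pruned by greedy
p-value-ordered clumping at r² > 0.001 within 10,000 kb (ties on p break
lexicographically by rsID, making clumping order-invariant).  The LD
source is an abstraction: a user-supplied pairwise r² table, or an
assume-independent mode for pre-clumped and simulated panels — no
genotype reference panel is ever required.  Per-SNP strength is
F_j = (β̂_Xj/σ_Xj)²; the summary is mean F with a 95% normal-theory lower
bound (mean − 1.96·SD/√k), with a percentile-bootstrap alternative, since
the reporting convention ("mean with lower bound") does not pin the CI
method.  Variance explained is Σ F_j/(F_j + n_j − 2) when n is known.

Harmonization aligns every source to the exposure's effect allele:
identical alleles are kept; swapped alleles negate the beta and mirror
the EAF; strand complements are resolved through A↔T/C↔G; palindromic
SNPs (A/T, C/G) are oriented by effect-allele frequency only when both
frequencies are known and outside the ambiguity window [0.42, 0.58]
(a common field convention — the quantity is configurable because no
single standard exists), otherwise dropped.  Missing frequencies drop
all palindromic SNPs — conservative by design.  Multi-exposure
harmonization takes the union instrument panel and *drops* (never
zero-fills) SNPs absent from any source: zero-filling would fabricate
null associations and bias direct effects toward zero.  Every candidate
SNP receives exactly one audit action (kept / sign_flipped /
strand_complemented / dropped:reason), and counts are conserved:
kept + dropped = candidates.

## Synthetic generator

The generator emulates the two-sample summary-statistic abstraction the
estimators consume:

* m independent SNPs (post-clumping by construction; no LD is simulated),
  allele frequency f ~ U(0.05, 0.95), 20% palindromic allele pairs to
  exercise harmonization;
* per-allele exposure effects scaled so the panel explains a configurable
  variance fraction (default 0.10, the order of the polygenic signal
  reported for the motivating exposure);
* true outcome effects θ·b_j plus horizontal pleiotropy α_j ~ N(μ_α, σ_α²)
  applied *in the exposure-increasing allele orientation* and optionally
  confined to a fraction of SNPs.  Oriented pleiotropy is the standard
  design for studying directional pleiotropy: an orientation-free offset
  self-cancels under Egger's β̂_X ≥ 0 convention and would be undetectable
  by construction;
* observation noise with SE (2f(1−f)·n_eff)^(−1/2), independently for the
  two samples; for the binary outcome n_eff = n·v(1−v) with case fraction
  v (default 0.12, a register-cohort scale), i.e. the logistic-regression
  information.  This matters: treating a 12%-case binary GWAS as if it had
  continuous-trait precision understates outcome SEs ~3-fold and breaks
  CI calibration of every ratio estimator;
* defaults mirror the motivating study: θ = ln(0.524) ≈ −0.646 per SD,
  m = 224, n_exposure = 766,345, n_outcome = 50,264;
* a mediation mode (exposure B loads on exposure A with λ = 0.66 and has
  zero direct outcome effect) and a bidirectional mode (each trait with
  its own instrument set, each observed once in its own sample) for the
  attenuation and directionality analyses;
* one integer seed; per-trait noise uses independently spawned streams,
  giving exact two-sample independence and byte-identical reruns.

What the generator does **not** emulate: LD between instruments, winner's
curse beyond what explicit selection induces, population stratification,
sample overlap between exposure and outcome, allele-frequency differences
between cohorts, or strand-annotation errors beyond the palindromic
ambiguity.  Passing tests therefore demonstrate correctness of the
estimators and workflow under the model's own assumptions, not robustness
to those artifacts in real data.

## Numerical choices and degenerate inputs

* Wald ratio requires β̂_X ≠ 0; IVW requires k ≥ 2, Egger/median/mode
  k ≥ 3, MR-PRESSO k ≥ 4, MVMR k ≥ p+2 (Egger p+3) — each violation is a
  typed error naming the remedy.
* p-values of exactly 0 in inputs are clamped to the smallest positive
  float with a warning (GWAS exports underflow).
* The GWS threshold is a strict inequality, as printed conventions state.
* Weighted-median interpolation clips to the outermost ratios; a single
  dominant weight returns that SNP's ratio.
* The mode grid is fixed at 512 points; all-equal ratios short-circuit to
  that value.
* WLS is solved by normal equations on the weighted design; the
  random-effects σ uses the unscaled bread matrix, which is why the fit is
  written in closed form rather than through a generic regression API
  (verified against statsmodels WLS in the tests).

## Problem sizes

The test suite exercises the full battery at m = 40–224 SNPs and effective
sample sizes 10⁴–10⁵, with 100–500 replicates for calibration and
recovery checks and bootstrap sizes of 50–300 inside replicated studies
(1000 at the user-facing defaults); the acceptance script uses 20–100
replicates per quantity.  These sizes make the whole suite run in a few
minutes on one CPU while keeping Monte-Carlo error well inside the
asserted margins.

## Known limitations

* rsID-only matching; no genome-build liftover or proxy-SNP lookup.
* The Steiger r² is an observed-scale approximation for binary traits.
* The weighted mode's bootstrap CI is conservative (see above).
* Real-data column-map presets are best-effort; portals change headers
  between releases, so the map is always user-overridable.
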