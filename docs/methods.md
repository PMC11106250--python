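# Methods

This note documents the statistical procedures implemented in `mrmediate`,
their defaults, the synthetic-data generator's assumptions, and the design
choices made where conventions differ between MR toolkits.

## Data model and harmonization

A summary-statistics table holds one row per variant: rsID, chromosome,
1-based GRCh38 position, effect/other allele, effect-allele frequency
(EAF), beta, SE, p-value and sample size.  Betas are per-allele effects in
trait units for continuous traits and log-odds for binary ones.  Rows with
non-positive SE, p outside (0, 1], EAF outside [0, 1] or identical alleles
are rejected (strict mode) or skipped and counted (lenient mode).
Delimiters are auto-detected among tab/comma/whitespace; scientific
notation and the unicode minus sign are normalised.

Harmonization aligns the outcome study to the exposure study's effect
alleles, matching variants by rsID:

* identical allele pairs (directly or on the complementary strand) are kept;
* swapped pairs have the outcome beta negated and EAF reflected
  (`flipped`);
* palindromic pairs (A/T, C/G) cannot be resolved from alleles alone.  They
  are resolved by frequency when unambiguous — dropped if
  min(EAF, 1−EAF) > 0.30 in either study (a configurable convention shared
  with widely used harmonization tools; the ambiguity limit is not a
  quantity with a single field-wide value), flipped when the two EAFs fall
  on opposite sides of 0.5, kept otherwise;
* a missing EAF on a palindromic pair forces a drop; a missing other allele
  downgrades matching to the effect allele only and tags the pair
  low-confidence;
* any other allele combination is dropped as incompatible.

Allele flipping is an involution and harmonization is idempotent; both are
property-tested.  Every input variant is accounted for as
kept/flipped/dropped/unmatched, and unmatched exposure variants feed the
proxy search.

## Instrument selection

* **Significance filter:** strict p < 5e-8 by default.
* **LD clumping:** greedy index-variant selection — visit variants by
  ascending p (ties: position, then rsID, making the result independent of
  input order), keep the best remaining variant, discard all others on the
  same chromosome within 10 Mb with r² ≥ 0.01 to it.  Variants unknown to
  the LD reference are treated as independent (r² = 0).
* **Proxies:** an instrument missing from the outcome study may be replaced
  by the donor variant with maximal r² ≥ 1.0 (complete LD by default;
  configurable), ties broken by position distance then rsID.
* **Instrument strength:** per-variant F = (beta/SE)².
* **Steiger directionality:** a variant is retained only if it explains
  strictly more variance in the exposure than in the outcome.  Variance
  explained is 2·EAF·(1−EAF)·beta² for standardized continuous traits; for
  binary traits the log-odds beta is converted to a latent-scale pseudo-r²,
  x/(x + π²/3).  The naive log-odds-scale formula is available as a
  sensitivity switch, since toolkits differ here.  Outcome-side EAF falls
  back to the exposure EAF when missing.

## Univariable estimators

All estimators consume harmonized pairs; ratio SEs use the first-order
delta method (the second-order term is omitted).  Confidence intervals are
normal-theory 95%; Egger inference uses the normal reference by default
(t optional).  Every bootstrap takes an explicit seed and is
bit-reproducible.

* **IVW:** weighted mean of Wald ratios (equivalently origin-constrained
  WLS of outcome on exposure betas with weights 1/SE_out²).  The
  random-effects variant inflates the fixed SE by √max(1, Q/(J−1)) —
  multiplicative overdispersion, matching the convention of the standard
  two-sample MR tooling; an additive random-effects model is deliberately
  out of scope.  A single instrument degenerates to the Wald ratio and is
  labelled as such.
* **Cochran's Q:** Σ w_j(θ_j − θ̂)², df = J−1, upper-tail chi-square.
* **MR-Egger:** pairs oriented so exposure betas are non-negative, WLS with
  intercept, weights 1/SE_out²; SEs carry √max(1, RSS/(J−2)) (dispersion
  never shrunk below 1).  The intercept estimates directional pleiotropy.
  Needs J ≥ 3.
* **Weighted/simple median:** ratios ordered with cumulative-weight
  percentile positions p_j = (S_j − w_j/2)/S_J and linear interpolation at
  0.5; the simple median sets all weights equal.  SE: standard deviation
  over 1000 parametric-bootstrap resamples θ_j* ~ N(θ_j, se_j).
* **Weighted mode:** argmax on a fixed 1024-point grid of the weighted
  normal-kernel density of the ratios with modified Silverman bandwidth
  φ·0.9·min(sd, IQR/1.349)·J^(−1/5), φ = 1 by default; identical ratios
  short-circuit to the common value.  Bootstrap SE as above.
* **Maximum likelihood:** b_Xj ~ N(ξ_j, SE_Xj²), b_Yj ~ N(θξ_j, SE_Yj²)
  with independent errors.  The profile objective
  Σ (b_Yj − θ b_Xj)²/(SE_Yj² + θ²SE_Xj²) is minimised from the IVW start;
  the SE comes from the observed information for θ (Schur complement over
  the nuisance ξ).  Non-convergence raises an explicit error.
* **Leave-one-out:** random-effects IVW re-estimated excluding each variant
  in turn, plus the all-variant row.

Degenerate panels are downgraded, never silently: J = 1 leaves the Wald
ratio only; J = 2 adds IVW/ML/Q/leave-one-out; J ≥ 3 adds Egger, medians
and mode; J ≥ 4 enables MR-PRESSO.

## MR-PRESSO

Observed residual sum of squares uses leave-one-out IVW predictions:
RSS = Σ_j w_j (b_Yj − θ̂₋j b_Xj)², w = 1/SE_Y².  n_sim (default 1000)
replicate datasets are drawn under the no-pleiotropy model
(b_Yj* ~ N(θ̂₋j b_Xj, SE_Yj), b_Xj* ~ N(b_Xj, SE_Xj)) and RSS recomputed
identically.  Empirical p-values use the +1 correction
(1 + #{sim ≥ obs})/(n_sim + 1), so they are never zero.  Per-variant terms
give outlier p-values, Bonferroni-adjusted over J (configurable to none);
flagged variants are removed for the corrected random-effects IVW
estimate.  The distortion test compares the relative change between raw
and corrected estimates against re-estimates after removing the same
number of randomly chosen variants, two-sided.

## Multivariable MR and conditional instrument strength

`MVMRDataset` holds the L×K exposure-beta matrix with SEs and the length-L
outcome vector, all aligned to the first exposure's effect alleles.  The
cross-exposure sampling correlation defaults to zero (non-overlapping
samples — the package's default study design keeps exposure, mediator and
outcome GWAS disjoint); a correlation matrix is accepted.

* **MVMR-IVW:** no-intercept WLS, weights 1/SE_out², SEs inflated by
  √max(1, Q/(L−K)).  K = 1 reduces exactly to univariable IVW.
  Rank-deficient exposure matrices raise a collinearity error naming the
  offending columns.
* **MVMR-Egger:** rows sign-oriented on a chosen exposure, WLS with
  intercept (the pleiotropy term), df = L−K−1.
* **MVMR-Lasso:** the IVW regression augmented with one L1-penalised
  per-variant intercept α_j (slopes unpenalised), solved by coordinate
  descent (soft-thresholding of the weighted residuals).  Over a
  decreasing geometric λ grid from λ_max (60 points spanning four
  decades), variants with α_j = 0 form candidate valid sets; the largest
  set whose post-selection IVW heterogeneity Q is within the
  chi-square(0.95) bound at its df is selected, and the final estimates
  are post-selection MVMR-IVW on it.  The selected λ and retained variants
  are reported.  The λ-selection rule is this package's design choice; the
  heterogeneity-stopping criterion was picked because it degrades
  gracefully to "keep everything" on clean data.
* **Conditional F:** weighted no-intercept regression of the target
  exposure's betas on the other exposures' betas, weights from the target
  exposure's SEs (refined once with the delta-method residual variance
  when a cross-exposure correlation is supplied);
  F = Q_x/(L − K + 1) with Q_x the weighted residual sum of squares.  The
  denominator was chosen so the K = 1 case equals the mean per-variant
  (beta/SE)² — a deliberate interpretation, documented because published
  formulations vary; perfectly collinear exposures give F ≈ 0.

**Instrument pooling:** for a model with several exposures, the union of
each exposure's genome-wide-significant variants is scored by its minimum
p across exposures, clumped once, and restricted to variants present (or
proxy-resolvable at the same complete-LD default) in every exposure and
the outcome.  The "iterative" pooling described in the applied literature
is resolved here as union → min-p scoring → single clump pass →
completeness filter.  Pooled sets are rebuilt per outcome, since outcome
availability differs between datasets.

## Mediation workflow

For each (exposure source, outcome) pair the univariable panel runs every
feasible method with heterogeneity, Egger-intercept, leave-one-out and
MR-PRESSO diagnostics, logging in/out counts at every stage (selection,
clumping, proxy substitution, harmonization, Steiger).  The mediator scan
fits one two-exposure MVMR per (mediator, outcome).  A mediator is flagged
as putative under the **attenuation rule** (default): the unadjusted
exposure estimate is significant (p < 0.05) but the mediator-adjusted
estimate is not, in at least one outcome dataset.  An alternative rule —
the mediator's own conditional effect on the outcome is significant — is a
config switch; the attenuation reading was chosen because it is the
operational pattern the workflow is designed to detect (adjustment
abolishing the exposure-outcome association).  All flagged mediators then
enter one joint MVMR model per outcome.

Significance is classified per estimate: `significant` when
p < round(0.05/n_exposures, 3) (0.017 for the default three exposures),
`suggestive` when p < 0.05, `null` otherwise; the classes partition.

Reports serialize to TSV tables plus a JSON bundle and a provenance
sidecar (config echo, seed, package version); output is deterministic
byte-for-byte given the same inputs and seed, and infeasible analyses
appear as explicit `unavailable` rows.

## Synthetic-data generator

The generator draws summary statistics directly at the summary level — no
individual genotypes — under the diagram
instruments → exposure → mediators → binary outcome with an optional
direct path and per-variant pleiotropy.  Study-size defaults mirror the
package's reference setting: a blood-proteome exposure GWAS (n = 35,892),
glycaemic/lipid-scale mediator GWAS (n = 200,622), and a case-control
outcome (n = 63,926, case fraction 0.344).  Instrument true effects are
γ_j = z_j·SE_Xj with z ~ U(5.5, 21), spanning per-variant F of roughly
30–450 — the strength range of the packaged osteocalcin instruments — so
instruments pass the 5e-8 filter in expectation; effect alleles are
generated exposure-increasing, and EAFs are uniform on (0.1, 0.9).  Each
of the K mediators has 15 instruments of its own at the same z range.
Standard errors follow se = 1/√(2·n·p(1−p)) for standardized continuous
traits and se = 1/√(2·n·p(1−p)·v(1−v)) for the binary outcome (case
fraction v, log-odds scale); observed betas add independent normal noise
at those SEs, with exposure, mediator and outcome noise mutually
independent (two-sample, non-overlapping designs).  `noise_scale = 0`
gives exact betas for analytic limit tests.

Pleiotropy models: `balanced` (α ~ N(0, σ²)), `directional`
(α ~ N(μ, σ²)) on a configurable fraction of exposure instruments,
`inside_violating` (α correlated with γ), and planted gross outliers whose
Wald ratio is multiplied by a configurable factor (default 10).

Two presets define the reference mediation scenarios, both with total
effect anchored at θ_t = −0.19 (odds ratio ≈ 0.83 per unit exposure):

* **full mediation** — θ_d = 0, τ = (−0.40, −0.45), ρ = (0.25, 0.20), so
  two mediators carry the whole effect in roughly equal shares; adjusting
  either alone leaves a non-significant remainder and adjusting both nulls
  the estimate;
* **partial mediation** — θ_d = −0.10 with the same τ and
  ρ = (0.15, 0.10).

What the generator does **not** emulate: LD between generated instruments
(an AR(1) LD block generator exists separately for clumping/proxy tests),
realistic allele-frequency spectra, winner's-curse selection bias,
sample overlap between studies, and liability-scale effects for the binary
outcome (betas are generated directly on the log-odds scale).  Passing
tests therefore certify the estimators and workflow under clean two-sample
assumptions, not robustness to those real-data complications.

## Reference study sizes and numerical choices

The calibration module (and `scripts/acceptance.py`) uses these study
sizes, chosen to give small Monte-Carlo error while keeping a full run
around a minute on one CPU: 200 random instances per WLS-oracle check
(agreement ≤ 1e-10), 5000 replicates for Q's type-I error (the null
scenario sets the causal effect to zero so the statistic's chi-square
calibration is isolated from the second-order exposure-noise term), 1000
replicates for IVW coverage, 500 seeds for the pleiotropy-robustness and
Egger-recovery studies (40% contamination at α = 0.05, respectively 100%
at μ_α = 0.02), 100/500 seeds for MR-PRESSO detection power (J = 11, one
planted 10× outlier, n_sim = 1000) and null size, and 200 runs for each
mediation preset.

Numerical details: empirical p-values are +1-corrected; optimisation for
the ML estimator is Nelder-Mead at 1e-10 tolerance from the IVW start;
degenerate bootstrap SEs (all ratios identical) fall back to
min(se_j)/√J; zero-bandwidth mode estimates return the common ratio;
p-values generated from extreme z-scores are floored at 1e-300 to stay in
(0, 1].  All randomness flows through `numpy.random.default_rng` seeded
explicitly; identical seeds and inputs give bit-identical results,
including serialized reports.

## Known limitations

Indels and multi-allelic variants are out of scope, as are genome-build
liftover, LD estimation from genotype panels, additive random-effects
IVW, penalised/robust IVW variants, MR-RAPS, contamination-mixture
estimators, MVMR-median/PRESSO and weak-instrument-corrected MVMR.  The
conditional-F and Lasso-selection formulations are documented
interpretations (see above) rather than ports of any specific existing
implementation.  Real-data caveats listed for the generator apply to all
simulation-based guarantees.
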