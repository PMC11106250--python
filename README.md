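# mrmediate

Two-sample Mendelian randomization (MR) mediation analysis from GWAS summary
statistics.

`mrmediate` is for epidemiologists and statistical geneticists who want to
estimate the causal effect of an exposure (for example a blood protein such
as osteocalcin) on a disease outcome (for example Alzheimer's disease) using
genetic variants as instruments, probe that estimate with the standard
sensitivity suite, and then ask *how much of the effect runs through
candidate mediators* (glycaemic and lipid traits, say) using multivariable
MR.  Everything operates on summary-level data — per-variant effect sizes,
standard errors, p-values and allele frequencies — so no individual-level
genotypes are required.

## The model

For instrument $j$, let $\hat\beta_{Xj}$ (SE $\sigma_{Xj}$) be its
association with the exposure and $\hat\beta_{Yj}$ (SE $\sigma_{Yj}$) its
association with the outcome (log-odds scale for binary outcomes), after
harmonizing both studies to a common effect allele.  Each variant gives a
Wald ratio $\hat\theta_j = \hat\beta_{Yj}/\hat\beta_{Xj}$ with first-order
SE $\sigma_{Yj}/|\hat\beta_{Xj}|$, and the primary estimate is the
random-effects inverse-variance-weighted (IVW) combination

$$\hat\theta = \frac{\sum_j w_j \hat\theta_j}{\sum_j w_j},\qquad
w_j = \frac{\hat\beta_{Xj}^2}{\sigma_{Yj}^2},\qquad
\mathrm{se}(\hat\theta) = \Big(\sum_j w_j\Big)^{-1/2}
\sqrt{\max\!\Big(1,\tfrac{Q}{J-1}\Big)},$$

where $Q$ is Cochran's heterogeneity statistic.  Sensitivity estimators
(MR-Egger with its pleiotropy intercept, weighted/simple median, weighted
mode, maximum likelihood, and the simulation-based MR-PRESSO outlier test)
guard the three instrumental-variable assumptions; Steiger filtering and
leave-one-out analysis guard directionality and single-variant dominance.

Mediation is decomposed with multivariable MR (MVMR): regressing
$\hat\beta_{Yj}$ on the instruments' associations with the exposure *and*
the mediators gives the exposure's **direct** effect $\theta_d$, while
univariable MR gives its **total** effect
$\theta_t = \theta_d + \sum_k \tau_k \rho_k$
($\tau_k$: exposure→mediator, $\rho_k$: mediator→outcome).  Conditional
F-statistics diagnose instrument strength after conditioning on the other
exposures; MVMR estimates come from IVW, MR-Egger and an L1-penalised
(Lasso) variant that discards pleiotropic variants.

Instrument selection follows the standard recipe: genome-wide significance
($p < 5\times10^{-8}$), greedy LD clumping ($r^2 < 0.01$ within 10 Mb),
proxy substitution at complete LD ($r^2 = 1$) for variants missing from the
outcome study, allele harmonization with frequency-resolved palindromic
variants, and Steiger directionality filtering.

A seeded synthetic-data generator (`mrmediate.simulate`) draws whole
multi-trait summary-statistics studies under an explicit
exposure → mediators → outcome diagram with configurable pleiotropy, so
every procedure is testable end to end without external downloads.  A
packaged 13-variant blood-osteocalcin instrument table
(`mrmediate.load_ocn_instruments`) provides a realistic instrument geometry.

## Worked example

```python
from mrmediate import load_ocn_instruments, simulate_outcome, harmonize, UnivariableMR

ocn = load_ocn_instruments("ELDJARN")            # 10 osteocalcin instruments
ad = simulate_outcome(ocn, theta=-0.2, n=63_926,  # synthetic case-control outcome
                      case_fraction=0.344, seed=7)
pairs = harmonize(ocn, ad)                        # align effect alleles
results = UnivariableMR.from_harmonized(pairs).fit_all(n_boot=1000, seed=7)
print(results.summary())
```

```text
Univariable MR (10 instruments)
  ivw_random: theta=-0.2167 (se 0.0434), OR=0.805 [0.740-0.877], p=5.76e-07, n_snp=10
  egger: theta=-0.1392 (se 0.1151), OR=0.870 [0.694-1.090], p=0.227, n_snp=10
  weighted_median: theta=-0.2434 (se 0.0572), OR=0.784 [0.701-0.877], p=2.09e-05, n_snp=10
  simple_median: theta=-0.2428 (se 0.0668), OR=0.784 [0.688-0.894], p=0.00028, n_snp=10
  weighted_mode: theta=-0.2471 (se 0.0691), OR=0.781 [0.682-0.894], p=0.000349, n_snp=10
  max_likelihood: theta=-0.2172 (se 0.0438), OR=0.805 [0.739-0.877], p=6.96e-07, n_snp=10
  Cochran Q = 4.426 (df 9), p = 0.881
  Egger intercept = -0.0089 (se 0.0123), p = 0.467
```

The outcome was generated with a true effect of $\theta = -0.2$ per unit
exposure (odds ratio $e^{-0.2} \approx 0.82$): every estimator's confidence
interval covers the truth, heterogeneity is unremarkable ($Q$ p = 0.88) and
the Egger intercept shows no directional pleiotropy — exactly what a clean
instrument panel should produce.

The full workflow — univariable panels, per-mediator MVMR scan,
attenuation-based mediator selection and the joint model — is available as
`mrmediate.run_pipeline(...)` or from the shell:

```bash
mrmediate simulate --k-mediators 2 --theta-direct 0 \
    --tau -0.4 --tau -0.45 --rho 0.25 --rho 0.2 --seed 5 --out study/
mrmediate pipeline --exposure study/exposure.tsv \
    --mediator study/mediator_mediator_1.tsv --mediator study/mediator_mediator_2.tsv \
    --outcome study/outcome.tsv --seed 5 --out report/
```

`report/` then holds `uvmr_results.tsv`, `heterogeneity.tsv`, `loo.tsv`,
`mvmr_scan.tsv`, `mvmr_joint.tsv`, `presso.json`, `report.json` and
`provenance.json`, with per-stage instrument counts and a significance
class (`significant` below the Bonferroni threshold 0.05/3 = 0.017,
`suggestive` below 0.05) attached to every estimate.

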