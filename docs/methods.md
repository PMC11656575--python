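# Methods

`cpgmediate` implements an epigenome-wide mediation analysis of the
relationship between cumulative psychosocial stress and cardiometabolic
risk factors, together with a synthetic-data generator that makes every
stage testable without access to restricted cohort data.  This note
records the models, the defaults and why they were chosen, the numerical
conventions, and the known limitations.

## The causal model

For participant-level exposure `X` (cumulative stress, SD units),
candidate mediators `M_j` (CpG beta values, `j = 1..J`), outcome `Y`
(one cardiometabolic risk factor), and confounders `C` (age, sex,
education, measurement year, ancestry PCs, fasting where relevant), the
per-CpG mediation model is the standard pair of linear equations

    M_j = a0_j + alpha_j X + a_Cj' C + e_Mj
    Y   = b0_j + bX_j X + beta_j M_j + b_Cj' C + e_Yj

with independent Gaussian errors.  The mediation effect of CpG `j` is
the product `alpha_j * beta_j`; the proportion mediated divides it by
the total effect of `X` on `Y` (the Model-1 regression coefficient).
No exposure-mediator interaction is modeled, so the product estimator
and the total-minus-difference estimator coincide exactly on any fixed
dataset — a property the tests assert to 1e-10.

## Stress scoring

Twelve survey measures across six domains (acute life events, financial
strain, neighborhood stress, relationship stress, lifetime
discrimination, childhood adversity) roll up as: prorated measure score
(mean of answered items rescaled to the item count) for participants
answering at least 80% of a measure's items, missing otherwise;
z-scored measures summed within domain and re-standardized; the six
domain z-scores summed and re-standardized into the cumulative score.
Participants missing any measure are dropped (complete-case).  Sample
SD (n−1) is used throughout, which makes `{1,2,3} -> {-1,0,1}`.
Proration at the 80% bar follows standard psychosocial-scale scoring;
whether the threshold itself counts as complete is resolved with `>=`.

## Preprocessing

Methylation: per-CpG mean imputation, then winsorization at
`[Q1 − 3·IQR, Q3 + 3·IQR]` (type-7/linear-interpolation quantiles), then
per-CpG OLS residualization on estimated white-blood-cell proportions
(one cell type dropped against the sum-to-one constraint) plus plate and
position dummies, with residuals re-centered at the CpG mean.  Plate and
position enter as fixed effects rather than random effects: per-CpG OLS
residuals are deterministic, fast at 10^5 CpGs, and match the
random-effects adjustment in expectation for balanced designs; this is a
deliberate deviation from a mixed-model formulation.

Outcomes: values outside the same 3·IQR fences are removed (not
clamped — deliberately asymmetric with methylation); then medication
adjustment (systolic +15 and diastolic +10 mm Hg under
antihypertensives, LDL-C/0.7 and TC/0.8 under statins, HDL-C and TG
never adjusted, glucose observations excluded under diabetes
medication); then natural-log transform of glucose and CRP.  The stage
order is fixed and each idempotent step is a no-op on re-application.

## Composite-null MaxP test

The mediation null `H0_j: alpha_j * beta_j = 0` is a union of three
components — (alpha=0, beta=0), (alpha=0, beta!=0), (alpha!=0, beta=0)
— so the MaxP statistic `max(p_alpha, p_beta)` treated as uniform is
badly conservative.  The corrected p-value evaluates the mixture null
CDF

    P(MaxP <= t | H0) = (pi01 t + pi10 t + pi00 t^2) / (pi01 + pi10 + pi00)

The component fractions come from Storey-type tail estimators with
lambda = 0.5 applied to each p-value series separately
(`pi_a0 = #{p_alpha > 0.5} / (0.5 J)`, same for beta), combined under
independence of alpha- and beta-null membership.  This is the simplest
estimator satisfying the composite-null correction; it sits behind the
`NullProportions` interface so alternative estimators can be swapped in.
The additional finite-sample quantile adjustment for extreme tails used
by some mixture-null implementations is not reproduced; at large `J`
with an FDR threshold of 0.05 the parametric mixture CDF dominates
behavior, and the approximation is accepted as a design choice.
Benjamini–Hochberg FDR is applied to the corrected p-values; ties in
MaxP resolve by stable CpG-ID order.

Because the corrected p-value is a monotone transform of MaxP that is
pointwise no larger, the BH rejection set of the corrected test always
contains the naive one — the power gain is structural, and the
calibration tests verify uniformity under the double null and empirical
FDR control under the mixture.

The scan itself is vectorized via Frisch–Waugh–Lovell: the exposure and
covariates are projected out of `Y` and all mediator columns once, after
which each `beta_j` is a univariate regression.  A naive loop of two
regressions per CpG produces identical estimates and p-values (tested to
1e-10 on 50 CpGs); 10^5 CpGs complete in seconds.

Mediator columns whose residual variance after the projection is zero
(constant columns, or columns collinear with the design) are flagged
degenerate and skipped with an audit entry rather than aborting the scan.

## PC mediation

Correlated CpGs cannot have their per-CpG mediation effects summed, so
the scan-significant set is reduced to principal components, which are
mutually uncorrelated; the cumulative proportion mediated over
*significant* PCs is a lower bound on the joint mediation effect of the
set.  Choices:

- CpG columns are centered and unit-variance scaled before the PCA
  (beta-value variances differ by orders of magnitude); this is a
  modeling assumption of this package, and it is configurable.
- k = 10 PCs by default, k = 5 when fewer than 10 CpGs survive the scan
  (and never more than `min(n−1, p)`).
- PC signs follow the largest-|loading|-positive convention, making the
  decomposition deterministic.
- Per-PC ACME is the product of coefficients from `PC ~ X + C` and
  `Y ~ X + PC + C`; intervals are percentile bootstrap over participants
  (10,000 resamples by default in production configs; smaller in tests),
  seeded; degenerate resamples with constant exposure are redrawn and
  counted.  Percentile rather than BCa intervals: the simplest method
  consistent with a nonparametric bootstrap, and configurable.
- A PC is significant when its 95% CI excludes zero.

Simulation checks: with five mediators jointly mediating 40% of the
total effect, the cumulative significant-PC proportion recovers 0.4
within Monte Carlo error when the PCs span the mediator space, and never
systematically exceeds it with block-correlated mediators.

## De-biased LASSO multivariable mediation

The scan-significant CpGs (tens of sites, `p << n`) enter one outcome
model jointly.  The exposure and covariates are unpenalized — they are
design variables, not selection targets — implemented exactly by
projecting them out of `Y` and the mediator block before the L1 fit.
The penalty is chosen by 10-fold cross-validation at the 1-SE rule on
seed-fixed folds.  De-biasing uses the node-wise-regression correction:
each mediator column is lasso-regressed on the others with its own
CV-selected penalty, forming an approximate precision matrix `Theta`,
and

    beta_debiased = beta_lasso + Theta M'(y − M beta_lasso) / n

with standard errors `sigma_hat * sqrt((Theta Sigma_hat Theta')_jj / n)`
and two-sided normal p-values.  At zero penalty the node-wise
construction returns the exact Gram inverse and the de-biased estimator
*is* multivariable OLS, which anchors the `p << n` oracle test (max
absolute gap < 1e-6 at `p = 10`, `n = 2000`); at the CV penalty the
per-coefficient bias on nonzero effects stays within a few percent.

Each CpG's adjusted `p_beta` joins its scan `p_alpha` in the same
mixture MaxP test.  Null proportions are re-estimated on the selected
set only when it holds at least 100 CpGs; otherwise they are inherited
from the genome-wide scan, since tail estimators are unstable on sets of
a few dozen.

## Enrichment

Mediating CpGs are tested against the non-mediating background (all
scanned, non-significant CpGs — the default background; restricting it
further is the caller's choice) with two-sided Fisher's exact tests
under the minimum-likelihood convention (the p-value sums all tables
with the observed margins whose probability does not exceed the observed
one); this matches full hypergeometric enumeration, verified
exhaustively for all tables with total `n <= 40`.  Feature flags derive
from distances: promoter = signed TSS distance in `(-1500, 0]` bp
(upstream negative); CGI = distance 0; shore = `(0, 2000]`; shelf =
`(2000, 4000]`.  Enhancer, DHS and eQTM flags are consumed from the
user-supplied annotation table.  Odds ratios are sample cross-products;
the Haldane–Anscombe 0.5 correction applies to the displayed OR only
(flagged), never to the exact p-value.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with a truth table for evaluation:

- **Exposure and covariates**: a standard-normal latent exposure; age
  correlated with it at a configurable strength (default 0.2); sex,
  education, smoking, medication and fasting flags drawn at realistic
  marginal rates for an older US cohort; ten standard-normal ancestry
  PCs.  Survey items are built measure-by-measure from domain latents so
  that the scored cumulative stress tracks the latent exposure
  (correlation ~0.95); 0.5% of items are missing at random, producing
  roughly the 10–15% complete-case attrition such surveys show.
- **Mediators**: each CpG is assigned a composite-null category from the
  configured mixture (default 0.90 / 0.045 / 0.045 / 0.01).  Beta values
  are a latent Gaussian — baseline `U(0.2, 0.8)`, exposure effect
  `alpha` for alpha-active categories, linear cell-proportion and
  plate/position nuisance signal, block-exchangeable residuals (block
  size 10, rho 0.3, SD 0.05) — clipped into `[0.001, 0.999]` rather than
  logit-transformed, so `alpha` remains the linear-model coefficient
  except in the clipped tail.  The clip rate is recorded in
  `truth.attrs["clip_rate"]` and is ~0 at the default effect sizes.
- **Outcome**: `Y = direct_effect*X + sum_j beta_j M_j + noise`, with
  optional linear covariate terms.  Defaults `alpha = 0.05` beta-value
  units per SD stress and `beta = 10` outcome units per beta-value unit
  are chosen for testability — large enough that detection is possible
  at the simulated sample sizes, small enough that beta values stay in
  range; there is no canonical effect magnitude to emulate for real
  cohorts.
- All draws come from one counter-based (Philox) stream keyed by the
  seed, so every table is bit-reproducible across platforms.

What the generator does **not** emulate: array chemistry (no IDAT or
probe-level artifacts), genotypes, non-Gaussian outcome errors,
exposure measurement error, or CpG-specific effect-size heterogeneity
(all active alphas share one magnitude, likewise betas).  Passing tests
therefore demonstrate statistical correctness of the machinery under
the stated model, not robustness to real-data pathologies.

## Problem sizes in tests and the acceptance script

Calibration runs use `J = 10,000` CpGs at `n = 500` (uniformity) and
`n = 1000` (FDR/power, 50 replicates).  Mediation recovery and CI coverage use the analytic
sample size `n = 2668` with 200 (tests) or 100 (script) replicates and
500 bootstrap resamples; the PC lower-bound study uses 5 mediators at
`n = 1000` with 300 resamples.  The end-to-end run uses `n = 500`,
`J = 2000`.  These sizes were chosen so the full battery runs in
minutes on a single core while keeping Monte Carlo error well inside
the asserted tolerances.

## Known limitations

- The null-proportion estimator mildly underestimates `pi00` when
  beta-active mediators have moderate power (their p-values spread over
  (0, 0.5)); empirically FDR control is unaffected at the tested
  conditions, but the lambda parameter is exposed for sensitivity
  checks.
- When many mediators carry outcome signal, each one's marginal outcome
  model absorbs the others' contributions as residual noise; per-CpG
  power at epigenome scale is therefore intrinsically low, which the
  calibration study's detection counts reflect.
- Plate/position fixed effects assume reasonably balanced batches; badly
  unbalanced designs would favor a true mixed model.
- The de-biased LASSO stage requires `p < n` by contract; it is meant to
  run on the scan-significant set, not genome-wide.
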