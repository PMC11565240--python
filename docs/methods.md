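# Methods

## Nutritional states

Each subject-round is classified from anthropometric z-scores into four
mutually exclusive, exhaustive states.  Stunting is height-for-age z-score
(HAZ) below −2 SD.  Overweight uses the age-appropriate weight index:
weight-for-height z-score (WHZ) above 2 SD before age 5, BMI-for-age z-score
(BAZ) above 1 SD from 5 to 19 years, and BMI above 25 kg/m² after 19.  CSO is
both conditions in the same round; normal is neither.  All cutoffs are strict
inequalities — a record at exactly HAZ = −2 or BAZ = 1 is not malnourished —
and the age bands are half-open, with age exactly 19 assigned to the
BMI-for-age band (the growth reference for school-age children covers 5–19
inclusive).  The WHO restricted-application adjustment for extreme
weight-based z-scores (|z| > 3) is deliberately not applied; classification
uses the raw index.

z-scores may be computed from raw measurements via the LMS transform
z = ((x/M)^L − 1)/(L·S), switching to the limiting form z = ln(x/M)/S when
|L| < 1e-8 for continuity in L at zero.  Reference L/M/S tables are
user-supplied CSV (key, L, M, S) with linear interpolation between rows; no
reference tables are bundled.

## Four-state Markov model

The unadjusted model is a discrete-time, first-order, time-inhomogeneous
Markov chain on the four observed states: each between-round interval has its
own 4×4 transition matrix.  Because the states are fully observed, the
saturated MLE is closed-form — empirical transition frequencies
n_ij(t)/n_i(t) — with plug-in multinomial standard errors
sqrt(p(1−p)/n_i(t)) and no small-sample correction.  Rows with zero origin
count are reported as undefined (NaN, flagged), never imputed as zeros.  The
marginal trajectory is π(t+1) = π(t)·P(t) from the empirical baseline
distribution; under the saturated model this equals the raw round-wise state
frequencies exactly on complete-case data, an identity the test suite asserts
to machine precision.  No latent-state machinery, continuous-time embedding
or higher-order dependence is implemented.

## Two-state covariate models

Covariate effects are estimated per malnourished condition on a two-state
collapse that preserves each condition's marginal definition: the stunting
model groups {stunted, cso} against the rest, the overweight model
{overweight, cso}, and the CSO model cso against all else.  For each
condition, two binary logit models are fitted — entry (origin outside the
group) and exit (origin inside):

    logit P(destination in group | origin, x_t) = α(t) + β′x_t

with one intercept per interval (time-inhomogeneous baseline) and covariate
coefficients shared across intervals, so each covariate level yields a single
odds ratio.  Covariates are measured at the origin round of each interval.
Categorical covariates expand against fixed references: male, urban, ≤5
household members, poorest wealth quartile (Q1), maternal education ≤6 years.

Estimation is damped Newton–Raphson on the Bernoulli log-likelihood: the full
Newton step is halved until the log-likelihood does not decrease; convergence
when the maximum absolute score falls below 1e-8 or the maximum parameter
change below 1e-10, capped at 100 iterations.  Standard errors come from the
inverse observed information at the optimum; confidence intervals are Wald at
z = 1.96.  Complete separation is detected as coefficients diverging past
|β| = 15 and reported as non-estimable, as are directions with fewer than 5
events or 5 non-events — small CSO samples typically render the CSO-exit
direction non-estimable, and it is reported as such rather than with inflated
odds ratios.  The engine is cross-checked against an independent generic
logistic-regression implementation to 1e-6 in the test suite.

## Covariate selection

Candidates are screened by univariate logistic regressions of baseline
stunting and baseline overweight (Wald p per non-reference level; a candidate
passes if any level is significant at 0.05 for either outcome), then added to
the two-state transition model by greedy forward steps minimising AIC
(2k − 2·loglik), stopping when no addition improves it.  The "model AIC" for
a condition is the sum over its two independent direction likelihoods, with
the covariate entering both directions at each step.  AIC ties within 1e-9
break lexicographically on covariate name, making the ladder deterministic
and input-order invariant.  The full ladder is always reported; the default
final recommendation is the fully adjusted model, for consistency across
conditions whose small samples would otherwise select different subsets — a
switch returns the stepwise winner instead.  Forward-only; no backward
elimination, no BIC/AICc, no multiple-testing correction in the screen.

## Synthetic cohorts

The generator emulates a five-round child cohort (default: ages 1/5/8/12/15;
an older-cohort design at 8/12/15/19/22 is a `round_ages` override) at
cohort scale (default 2 000 subjects).  Baseline state prevalences default to
(74.5, 25.1, 0.2, 0.2)% and the default per-interval matrices encode the
canonical dynamics of such cohorts: stunting onset concentrated in ages 1–5,
stunting reversal rising through adolescence, overweight accumulating slowly,
CSO rare but sticky.

Covariates: sex (1:1) and maternal education (75% ≤6 years) are
time-constant; wealth quartile (uniform), residence (75% rural) and household
size (60% ≤5) evolve by a sticky Markov process — stay with probability 0.9,
otherwise redraw from the marginal — since real panel covariates change
slowly and their dynamics are not otherwise pinned down.

Covariate effects are injected on exactly the scale the fitting model uses:
for a subject whose covariate matches an effect's level, the total
probability mass of entering (or leaving) the target group is shifted on the
logit scale, with destinations inside and outside the group rescaled
proportionally — preserving row-stochasticity exactly.  When the baseline
matrices give every origin state outside the group the same group-entry mass,
the fitted two-state model is exactly correctly specified;
`balanced_group_matrices` constructs such dynamics and `benchmark_config`
packages the standard validation scenario (entry log-odds 0.693, i.e. OR 2.0,
of the wealthiest quartile on stunting entry).  Under the general default
matrices the injection is still exact per origin state but the shared
intercept averages over origin states, so recovery there is approximate by
construction.  Rows whose group mass is 0 or 1 cannot be shifted on the logit
scale and are left unchanged.

Anthropometry is drawn from truncated normals strictly inside the correct
side of every cutoff (margin 1e-6), so classification reproduces the
generating state on 100% of rows; means and SDs (e.g. HAZ −2.8 ± 0.7 for
stunted, −0.9 ± 1.0 otherwise) are typical of cohorts in settings with a
high stunting burden.  Attrition is monotone dropout — a per-interval
probability of being lost, never regained — MCAR by default with optional
covariate-dependent logit shifts, plus independent per-field item
missingness.  Complete-case retention therefore follows the closed form
(1−d)^(R−1).  All randomness flows from one seed through four spawned
streams (states, covariates, anthropometry, attrition), so each stage is
independently reproducible.

What the generator does **not** emulate: sentinel-site cluster sampling and
oversampling of poor areas (hence no survey weights), measurement error in
height/weight, informative missingness beyond the optional covariate-shifted
dropout, cohort-vs-age effects, or pubertal-timing deviations from the growth
reference.  Passing tests therefore validate the estimators under the model's
own assumptions, not robustness to these real-data features.

## Complete-case preparation and descriptive tables

The analytic sample is built by listwise deletion: subjects must have every
round with a classifiable state and (in covariate scope) complete covariates.
Each exclusion is attributed to its first failing reason in the fixed order
missing round → missing anthropometry → missing covariate, so reason counts
are unambiguous and conserve subjects.  Baseline tables use Pearson r×c
chi-squared tests without continuity correction; expected counts below 5 are
flagged; variables with a single observed level get an undefined p-value
rather than a fabricated one.  No imputation of any kind.

## Numerical choices and problem sizes

Validation simulations use cohort-scale or somewhat larger samples chosen so
Monte-Carlo error is small relative to the quantities checked: 10 000
subjects × 50 replicates for mean odds-ratio recovery, 5 000 × 200 for Wald
coverage, 2 000 × 100 for null calibration of the screen, and 50 000 for
frequency-vs-matrix agreement (3-sigma binomial bands).  Exact identities
(oracle equivalence, saturated marginals, intercept-only rates, AIC nesting)
are asserted at 1e-8 to machine precision on small fixtures.

## Known limitations

- Covariate effects on the initial-state distribution are not modelled; the
  baseline distribution is covariate-free.
- The two-state models give one OR per covariate across all intervals;
  interval-varying effects are absorbed into the interval intercepts only.
- Four-state multinomial covariate models (e.g. effects on stunted→overweight
  specifically) are out of scope.
- Under the general default dynamics the benchmark recovery is approximate
  (see above); exact recovery requires balanced group-entry dynamics.
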