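# dbmtransit

Multi-state transition analysis of the **double burden of malnutrition** in
longitudinal child cohorts.

Children in low- and middle-income countries increasingly face undernutrition
and overnutrition at once: a child can be stunted (chronically short for age),
overweight, or both at the same time (concurrent stunting and overweight,
CSO).  Cross-sectional prevalence hides how individuals move between these
conditions as they grow.  `dbmtransit` provides the full analysis pipeline
for studying those movements in panel data — for epidemiologists and
biostatisticians working with multi-round cohort studies of child growth.

## The model

Each subject is classified at every round into one of four nutritional states
from WHO-standard anthropometry (strict cutoffs):

| state | definition |
|---|---|
| stunted | height-for-age z-score HAZ < −2 SD |
| overweight | WHZ > 2 (age < 5 y), BMI-for-age z > 1 (5–19 y), BMI > 25 kg/m² (> 19 y) |
| cso | stunted **and** overweight in the same round |
| normal | neither |

Two model layers:

1. **Unadjusted four-state Markov chain** (first-order, time-inhomogeneous):
   for interval *t* the transition matrix has entries
   *P<sub>ij</sub>(t) = Pr(S<sub>t+1</sub> = j | S<sub>t</sub> = i)*.  With
   fully observed states the saturated MLE is the empirical frequency
   *n<sub>ij</sub>(t)/n<sub>i</sub>(t)* with plug-in SE
   √(p(1−p)/n<sub>i</sub>(t)); the marginal state distribution follows by
   forward propagation π(t+1) = π(t)P(t) and coincides exactly with the raw
   round-wise frequencies on complete-case data.

2. **Covariate-adjusted two-state transition models**, one per malnourished
   condition (stunted/not, overweight/not, CSO/not), with a binary logit
   parameterization:

   logit Pr(enter target | not in target at *t*, x<sub>t</sub>) = α<sub>e</sub>(t) + β<sub>e</sub>′x<sub>t</sub>

   and symmetrically for exit.  Interval-specific intercepts carry the
   time-inhomogeneity; covariate effects are shared across intervals, so each
   covariate level yields a single odds ratio exp(β) with 95% Wald CI —
   the multiplicative change in the odds of transitioning versus remaining.
   Estimation is damped Newton–Raphson on the Bernoulli likelihood;
   directions with fewer than 5 events, or complete separation, are reported
   non-estimable instead of as extreme ORs.

A synthetic-cohort generator produces panels with known state dynamics,
covariate effects injected on exactly the fitted logit scale, anthropometric
measurements consistent with each state, and monotone attrition — so the
whole pipeline validates against known truth without any external data.

## Worked example

```python
import dbmtransit as dt

# a 2000-child cohort observed at ages 1/5/8/12/15 with known dynamics
cfg = dt.default_config(n_subjects=2000, seed=1)
panel, truth = dt.simulate_cohort(cfg)
panel = dt.simulate_anthropometry(panel, cfg)

# classify from anthropometry, build the complete-case analytic sample
classified = dt.classify_panel(panel.drop(columns=["state"]))
analytic, log = dt.complete_case_filter(classified, scope="states_and_covariates")

# unadjusted four-state Markov fit
res = dt.FourStateMarkov(analytic).fit()
print(res.marginals.round(3))

# adjusted two-state model: odds ratios for transitions into/out of stunting
fit = dt.TwoStateTransitionModel(analytic, "stunting", ["sex", "wealth_q"]).fit()
print(fit.odds_ratios()[["direction", "term", "OR", "ci_low", "ci_high"]].head(4))
```

Output:

```
[[0.764 0.233 0.002 0.002]
 [0.623 0.338 0.03  0.009]
 [0.662 0.292 0.034 0.011]
 [0.696 0.243 0.045 0.015]
 [0.741 0.152 0.082 0.024]]
  direction          term        OR    ci_low   ci_high
0      into   sex[female]  1.049110  0.881976  1.247917
1      into  wealth_q[Q2]  0.823108  0.639485  1.059457
2      into  wealth_q[Q3]  0.988797  0.775755  1.260347
3      into  wealth_q[Q4]  0.958872  0.751439  1.223567
```

The marginal matrix gives the probability of each state
(normal/stunted/overweight/cso) at each of the five rounds: stunting peaks at
age 5 (33.8%) then recedes through adolescence as overweight accumulates —
the generator's default dynamics.  The ORs compare each covariate level with its reference
(male, poorest quartile Q1); with no generating covariate effects they hug
1.0, as here.

A command-line interface mirrors the stages:

```bash
dbm-transit simulate --n-subjects 2000 --seed 1 --out panel.csv
dbm-transit classify --panel panel.csv --out classified.csv
dbm-transit prepare  --panel classified.csv --out analytic.csv --table1 table1.csv
dbm-transit markov   --panel analytic.csv --out-dir markov/
dbm-transit adjust   --panel analytic.csv --out ors.csv
dbm-transit select   --panel analytic.csv --target stunting --out selection.json
dbm-transit run      --config run.yaml        # all stages, manifest included
```

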