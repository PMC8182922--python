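# Methods

This note documents the statistical models implemented in `ltfu`, the design
choices made where several defensible options existed, and what the synthetic
generator does and does not emulate.

## The estimation problem

A cohort of N surviving very-preterm children is assessed at 2 years of
corrected age through a parental questionnaire.  Let Y be the binary
composite impairment outcome, X the baseline covariates recorded at birth,
and R the response indicator.  Y is observed only when R = 1 and the
questionnaire items could be scored.  The estimand is the cohort prevalence
P(Y = 1).  The crude estimate P(Y = 1 | outcome observed) is biased whenever
response is associated with Y, directly or through X.

Missingness taxonomy used throughout: **MCAR** (missingness independent of
everything), **MAR** (independent of Y given observed X), **MNAR**
(depends on Y itself even given X).

## Outcome derivation

The composite outcome is gross motor impairment (any of three parent-report
items: unable to walk without assistance, unable to sit without support,
unable to hold the head up) and/or non-verbal cognitive (NVC) impairment,
defined as a PARCA-R NVC score — the sum of 34 binary items — strictly below
22 (the <2.5th-percentile cut-off in term-born norms).

* **No pro-rating.**  If any of the 34 items is missing the score, and hence
  the NVC flag, is missing.  Partial-score pro-rating rules vary across
  studies and would blur the downstream missing-data accounting; responders'
  outcome missingness is instead handled by the imputation machinery.
* **Kleene logic for the composite.**  The OR of the three motor flags and
  the NVC flag is 1 as soon as any observed component is 1, 0 only when all
  four are observed 0, and missing otherwise.  This classifies every child
  whose composite is determinable from partial data and is exhaustively
  property-tested against a brute-force completion oracle.
* **Eligibility.**  Deaths between discharge and 2 years, severe congenital
  anomalies, and deaf or blind children are excluded sequentially (each child
  counted under the first applicable reason), mirroring the usual cohort
  construction in which sensory-impaired children cannot be assessed with
  these instruments.

## Attrition description

`attrition_table` reports responders/non-responders and missing-data counts
(≥1 missing covariate; outcome missingness among responders) overall and per
region, with percentages recomputed from counts at render time (1 decimal,
half-up).  `association_scan` fits, for each baseline factor separately, a
maximum-likelihood logistic regression of the target (follow-up, or the
observed outcome among scored responders) on the factor's dummies plus
region-of-birth dummies, and reports a Wald block test of the factor's
coefficients.  Rows missing the factor are dropped per factor; the missing
category never enters the test.  A likelihood-ratio variant is available via
`test="lr"`.  The Wald default was chosen because it needs a single fit per
factor and is the convention in the general-purpose statistical packages this
pipeline emulates; on null simulations its type-I error sits at the nominal
level (checked at 0.05 over hundreds of replicates).  Complete separation is
reported as a missing p-value with a diagnostic flag rather than an
exception, so a scan over many factors never aborts.

## Multiple imputation by chained equations

Incomplete variables are the derived outcome and any covariates with missing
values.  Each is imputed from a conditional model given all other analysis
variables (region, follow-up indicator, covariates, outcome); the follow-up
indicator drops out of the outcome model automatically because it is constant
over the fitting rows — imputation for non-responders then rests on the
covariates, which is exactly the MAR assumption.

One Gibbs-style sweep imputes each variable in turn (visit order: increasing
fraction missing, so well-informed variables stabilise first); chains start
from random draws of the observed margins.  Binary variables use the
Bayesian logistic draw: ML fit on observed rows (Newton–Raphson; a 1e-4
ridge penalty is applied only when a fit separates, and such fits are
counted in the diagnostics), coefficient vector drawn from N(MLE, inverse
observed information), Bernoulli draw from the resulting probabilities.
Multi-level categoricals use the analogous posterior-draw multinomial logit;
continuous variables (none in the shipped generator) use predictive mean
matching with 5 donors.  The posterior draw, rather than a bootstrap refit,
makes the imputations "proper" at negligible cost; it matches the dominant
convention for binary imputation in the chained-equations literature.

**Delta adjustment.**  The MNAR sensitivity parameter δ is added to the
linear predictor of the outcome's imputation model before drawing, for *all*
rows being imputed — non-responders and responders with unscorable items
alike, since the sensitivity parameter is defined as the log-odds difference
between children with missing and with observed outcomes, without
distinguishing the two routes.  Because the odds ratio is symmetric, a
response model in which impairment lowers the response log-odds by δ implies
exactly a +δ log-odds excess of impairment among non-responders given X, so
re-imputing at the true δ removes the MNAR bias (verified by the anchoring
Monte-Carlo).  δ = 0 reproduces the MAR analysis bit-for-bit under the same
seed, because the offset enters the same code path as an additive 0.

**Defaults.**  m = 100 imputations (the headline analyses' convention) and
15 sweeps per imputation.  With the generator's missingness pattern (~3–4%
per covariate, ~51% outcome) the chains reach stationarity within 2–3
sweeps — initialisation from observed margins is already close to the
stationary distribution — so the repeated-cohort studies and the
reproduction script use m = 20 and 5 sweeps, and the chain-mean slope
diagnostic (`chain_slopes`) is exposed so users can verify stationarity at
any setting.  The m independent chains run on RNG streams spawned from one
seed: results are bit-reproducible and extending m never perturbs existing
imputations.

## Pooling

Per-imputation prevalences are pooled by Rubin's rules on the logit scale:
estimates and binomial variances are delta-method transformed, the pooled
mean, within-variance W, between-variance B and total T = W + (1 + 1/m)B are
formed, and a t-interval with Barnard–Rubin degrees of freedom (complete-data
df = n − 1) is back-transformed.  The logit scale keeps intervals inside
[0, 1] and makes the pooled machinery consistent with the crude estimator,
which uses the logit-scale Wald interval se = √(1/x + 1/(n−x)); a
proportion-scale option exists for comparison.  Estimates of exactly 0 or 1
receive a 0.5-success continuity adjustment (with a warning) before the
transform.  `percent_change` reports (corrected − crude)/crude × 100;
rounding is applied only at render time.

## Inverse-probability weighting

Candidate predictors are screened by their region-adjusted bivariate
association with follow-up at p ≤ 0.2 — deliberately liberal so that
variables associated with follow-up only conditionally on others can still
enter — and region is always retained.  The response model is a
maximum-likelihood multivariable logistic regression on the retained
predictors (complete rows); responders receive weight 1/p̂.  The weighted
prevalence is the Hajek ratio Σwy/Σw over responders with an observed
outcome, with the robust variance Σw²(y − p̂)²/(Σw)² that treats weights as
fixed — a mildly conservative-direction simplification; a bootstrap variance
is available.  Optional weight truncation at a percentile cap and stabilised
(marginal-numerator) weights are off by default, matching the plain
inverse-weight description this pipeline follows.

Two deliberate choices are worth flagging.  Responders whose outcome could
not be scored are *excluded* from the weighted mean: their weight corrects
for non-response, not for item missingness, and no published rule covers
them.  And in the imputed-predictor variant the outcome is excluded from the
imputation entirely (it stays observed-or-missing as in the input); each
completed dataset is screened, fitted and estimated independently, and the m
estimates are pooled by Rubin's rules.

## The synthetic cohort generator

Real cohort data of this kind cannot be redistributed, so the generator is a
first-class, tested component that emulates the *statistical structure* the
estimators rely on:

* two regions ("PT" 34.7%, "UK" 65.3%) and 11 categorical baseline
  covariates whose margins match the published descriptive table of a
  four-region European very-preterm cohort;
* a logistic outcome model in which neonatal factors dominate (male sex
  +0.69, gestational age 23–25 weeks +1.49, severe neonatal morbidity +1.21,
  Apgar < 7 +0.80 on the log-odds scale) with weaker social effects, and a
  logistic response model in which social factors dominate (young maternal
  age −0.90, third-or-higher birth −0.95, most-deprived quintile −1.21,
  no breastfeeding at discharge −0.65) and deprivation is deliberately null
  on the outcome — reproducing the pattern that deprivation predicts
  follow-up but not impairment;
* slopes were read off the published two-way tables as crude level odds
  ratios; the two intercepts were then calibrated once, by root-finding on
  400k-draw margins, to the published response rate (54.2%) and prevalence
  (18.4%), and frozen (2.2969 and −3.2991);
* attrition: MAR given covariates when `delta_true` = 0; `delta_true` = d
  subtracts d from the response log-odds of latently impaired children, so
  d = 0.4 encodes "impaired children ~1.5× less likely to respond";
* questionnaire items generated from latent status (impaired children draw
  an NVC score in 10–21 with weight 0.8 or a single motor flag with weight
  0.2; unimpaired children draw 24–34), then each of the 37 items flips with
  probability `item_error_rate`.  The default is 0.001: misreports of severe
  impairment are rare in parent questionnaires, and the generator's contract
  is that the derived outcome tracks latent status closely enough (net
  misclassification ~0.2 pp, dominated by motor false positives ≈ 3 × the
  item error rate) that estimator bias in the Monte-Carlo studies is
  attributable to missingness rather than measurement;
* outcome missingness among responders is region-specific (PT 4.7%,
  UK 15.9% → 11.1% overall), and per-covariate MCAR missingness at the
  published per-variable rates leaves ~14.4% of rows incomplete.

What the generator does **not** emulate: the real joint covariate
distribution (covariates are drawn independently within region),
gestational-age-specific survival, family-level clustering of multiples
(children are independent, an explicit simplification — the family/child
level of non-response is unknowable from published material), or individual
socioeconomic measures behind the area-deprivation quintile.  Passing
Monte-Carlo suites therefore demonstrate correctness of the estimators under
a faithful *marginal* structure, not performance under real-world covariate
dependence.

## Monte-Carlo evaluation

`ltfu.evaluation` packages the repeated-cohort studies: estimator bias under
MAR (MI and IPW near-unbiased, complete-case biased low), MNAR anchoring
(δ-adjusted imputation at the true δ removes the bias the MAR analysis
leaves), delta-grid monotonicity, and null calibration of the scan/screening
p-values.  The shipped problem sizes — 50 replicate cohorts of n = 3000 with
m = 20 and 5 sweeps for the recovery studies; 3 seeds of n = 1500 with
m = 10 for the grid; 200 replicates of n = 400 for null calibration — are the
package's chosen trade-off between Monte-Carlo error (bias SE ≈ 0.1 pp for
the recovery studies) and runtime on a single CPU.  All studies spawn
per-cohort seeds from one master seed.

## Numerical details and edge cases

* Newton–Raphson logistic/multinomial with warm starts across sweeps;
  divergence or a singular information matrix triggers the 1e-4-ridge refit
  and a diagnostic counter.
* Predictor columns constant over a model's fitting rows are pruned from fit
  and prediction alike (the follow-up flag in the outcome model being the
  canonical case).
* Categorical levels unobserved in a fitting subsample are dropped from that
  multinomial model and never imputed (warned).
* A variable with a single observed class is imputed as that constant
  (warned); a variable 100% missing is a configuration error.
* Same-seed grids: every delta scenario re-runs the sampler from the same
  seed, so scenario differences are attributable to δ alone and the grid is
  empirically monotone per seed, not just in expectation.
* Display rounding (1 decimal, ties away from zero) happens only in report
  rendering; all comparisons and pooling use full precision.

## Known limitations

* The sandwich IPW variance ignores the uncertainty of the estimated
  weights and of the screening step (bootstrap available but slow).
* The delta offset is a constant (pattern-mixture with a single shift);
  selection-model or covariate-dependent-δ sensitivity analyses are out of
  scope.
* The imputation engine models categorical and continuous variables only;
  counts, ordered-logit links and multilevel structure are not implemented.
* Barnard–Rubin degrees of freedom are the only small-sample refinement
  applied; no multiplicity adjustment across the factor scan (none is
  conventional for this descriptive step).
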