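# Methods

`pph_cea` implements a within-trial economic evaluation of early detection of
postpartum hemorrhage (PPH) with a calibrated blood-collection drape plus a
bundled first response (uterine massage, oxytocic drugs, tranexamic acid, IV
fluids, examination/escalation), against usual care, in a parallel
cluster-randomized design with a baseline control phase across hospitals in
Kenya, Nigeria, South Africa and Tanzania.  The perspective is the public
healthcare system; outcomes are cost per severe PPH (blood loss >= 1,000 ml)
averted and cost per DALY averted, in 2022 USD.  Because the trial's
patient-level data are not public, the package includes a first-class
synthetic-trial generator calibrated to the published aggregate results; all
estimators are exercised and validated on that generator.

## Outcome models

All fixed effects in the design are constant within a hospital-period cell,
so records are reduced without loss to cluster-period sufficient statistics
(event counts; outcome means and within-cell sums of squares).

**Constrained baseline.**  The treatment indicator is
`arm == intervention AND phase == implementation`; it is identically zero in
the baseline phase, so both arms share a common baseline expectation and the
treatment effect is identified from post-randomization divergence, adjusted
for baseline imbalance.  Fixed effects: intercept, treatment exposure, period,
country, and three cluster-level randomization covariates (annual vaginal
births, baseline severe-event proportion, baseline oxytocin quality),
z-scored across clusters for conditioning.  Random effects: cluster intercept
and cluster-by-period intercept.

**Severe PPH (binomial/logit).**  Laplace-approximate maximum likelihood.
For fixed variance components (sigma_c, sigma_p), the fixed effects and
random-effect modes solve a jointly penalized Newton system; the
cluster-by-period block is diagonal and the cluster block becomes diagonal
after a Schur complement, so each Newton iteration costs one dense p x p
solve.  The two standard deviations are profiled by Nelder-Mead on the
Laplace criterion (penalized log-likelihood minus half the log-determinant
of the random-effect Hessian).  Standard deviations are floored at 1e-4;
estimates within 10x of the floor are reported as boundary cases.  Linear
predictors are clipped at +-30 and near-separation is flagged; robust
inference is still returned in that case.

The adjusted risk difference comes from marginal standardization: predicted
risks are averaged over the analysed sample (cell-size weighted, both
phases) with the exposure set to 1 and 0 and random effects at their
conditional mode of zero ("population-median" standardization; integrating
over the random-effect distribution is a config alternative we did not make
default).  CIs are delta-method on the cluster-robust covariance.

**Costs and DALYs (Gaussian/identity).**  REML on cell means: the residual
variance is the pooled within-cell variance (closed form), and the two
variance components are profiled by L-BFGS-B on the cell-mean restricted
likelihood, where a cell mean carries residual variance sigma_e^2/n_cell.
This is numerically identical to a full REML fit on individual records
(checked against `statsmodels` MixedLM to ~4 decimals on fixtures) but fast
enough to sit inside permutation and bootstrap loops.

**Cluster-robust covariance.**  Both families report a sandwich covariance
with hospitals as independent units, built from per-cluster profile scores.
With G clusters and p (all cluster-level) fixed effects, the score outer
product is scaled by G/(G-p) and Wald CIs use t(G-p) critical values; plain
CR1 visibly under-covered in calibration runs at G = 40 (empirical SD of the
risk difference ~12% above the CR1 SE), and this df-style correction
restores ~92-95% coverage.  No Kenward-Roger-type correction is attempted.

**Permutation CIs (Gaussian outcomes).**  Per-patient costs and DALYs are
heavily right-skewed (cost s.d. ~3x the mean; DALYs are near-zero for
survivors and ~20+ for deaths), so CIs for the adjusted mean differences
invert nonparametric permutation tests.  H0: effect = delta is tested by
subtracting delta from treated cells and re-estimating the treatment
coefficient under re-randomized cluster arm labels within country strata
(the minimization algorithm that produced the actual allocation is not
reproducible; country is the dominant stratifier, and cluster-level
permutation respects the design).  Two-sided p-values use (b+1)/(n+1) for
sampled permutations and the exact proportion under exhaustive enumeration,
which replaces sampling whenever the number of distinct within-stratum
assignments is small (<= 20,000 and <= 20x the requested replicates).  CI
bounds are found by bisection in delta to a tolerance of 1e-3 x the outcome
s.d.  In the default fast mode the variance components are frozen at the
observed-data estimates, making the permuted statistic affine in delta, so
the full inversion costs one pass over assignments; a full-refit mode exists
and agrees on fixtures.  Model-based Wald CIs are retained alongside for
comparison.

**Multiple imputation.**  Only blood loss is incomplete (~2%, records
without source verification), so chained equations collapse to a single
predictive-mean-matching step: the linear predictor is refitted on a
bootstrap resample of complete cases (proper imputation), with treatment
exposure, period and cluster indicators among the predictors (the cluster
indicator is the clustering allowance); donors are the 10 nearest complete
cases by predicted value.  Seven completed datasets are analysed like the
base case and pooled by Rubin's rules with Barnard-Rubin degrees of freedom.
Within-imputation inference is the robust Wald variance: nesting permutation
inversion inside MI would compound two resampling loops for no benefit at
this missingness level.

## DALY engine

YLD = disability weight x 6/52 years, with weights 0.324 (severe PPH,
>= 1,000 ml) and 0.114 (less severe PPH, 500-999 ml); thresholds are closed
lower bounds.  Deaths from bleeding contribute discounted years of life
lost: (1 - e^{-rL})/r at r = 3%/year, with L the linearly interpolated
remaining female life expectancy at the age of delivery from the country's
abridged life table (the r -> 0 limit is L; verified numerically).  Deaths
replace, rather than add to, the 6-week morbidity (avoids double counting;
the difference is < 0.04 DALYs per death); the 6-week YLD is not itself
discounted (< 0.2% effect); no age weighting.  The shipped life tables are
synthetic but plausible for these four countries; real abridged tables can
be supplied as CSV.

## Costing engine

Unit costs are assembled per item: raw price -> USD at the price-year
exchange rate -> inflated to 2022 with US CPI factors (conversion precedes
inflation, the preferred order when imported commodities dominate) -> a 25%
markup on traded goods only (drapes, drugs, IV fluids, garments, commercial
tamponade devices; not services, personnel or bed-days) -> market-basket
transfer to countries without data (cost x index ratio, using a relative
inpatient/outpatient service-delivery index; transitive by construction) ->
derivation rules: laparotomy = 80% of hysterectomy; bimanual compression and
physician attendance priced at the per-minute rate of the lowest-grade
doctor who could attend a severe PPH; uterine massage and examination cost
zero (reprioritized staff time).  Per-patient cost is the inner product of
resource quantities with the country's unit costs; a component vector is
retained and sums exactly to the total.  Costs are not discounted (short
within-trial horizon).  All shipped prices, exchange rates, CPI factors and
basket indices are synthetic defaults, labelled as such in the config files;
the real extended unit-cost tables are not public.

The drape-price DSA rebuilds the unit-cost table at 1.00/0.75/0.50 USD
(2023 prices, re-applying the 2022 adjustment and markup), re-fits the cost
model, and holds the DALY results fixed (drape price cannot enter DALYs).

## Decision outputs

Incremental effects are stored as averted quantities (positive = health
gain).  ICER = dC/dE when the signs form a genuine trade-off; dC < 0 with
dE > 0 is dominant, the reverse dominated, dE = 0 undefined (serialized as
an explicit `"undefined"` marker, never NaN text).  The CEAC is the fraction
of clustered-bootstrap pairs with positive net monetary benefit
lambda x dE - dC over a lambda grid (default 0-5,000 USD/DALY in steps of
25).  Bootstrap replicates resample clusters with replacement within
country x arm strata — every replicate keeps all four countries and both
arms, preserving the fixed-effect structure — carrying each resampled
cluster's full two-phase record set, and re-fit both Gaussian models; the
cost/DALY pairing is preserved within replicate.  Failed replicates are
dropped and counted (> 5% triggers a warning).

Willingness-to-pay thresholds: per-country 1x GDP per capita, and
opportunity-cost thresholds at 51% of GDP per capita (Kenya, Nigeria,
Tanzania) or 71% (South Africa); weighted versions use hospital-count
weights.  With approximate public 2022 GDP-per-capita values the weighted
thresholds are ~2,828 and ~1,685 USD per DALY averted.  Country-level
results are fully pooled one-country costing CUAs: every patient re-costed
and re-DALYed with one country's tables, models re-fit with the main
adjustment set, ICER judged against that country's thresholds.  Budget
impact is the adjusted per-birth cost difference times annual vaginal-birth
volume, per country and total.

## Synthetic-trial generator

The generator is the package's stand-in for the study conditions: 78
hospitals (14/38/14/12 by country, 1:1 arms within country), two 7-month
phases, per-cluster phase sizes drawn uniformly from 800-1,900 births
(~210k births in total), 2% missing (unverified) blood loss.

* **Events.**  Severe PPH and PPH carry logit-scale random cluster
  (sd 0.30) and cluster-by-period (sd 0.15) intercepts, shared across the
  two severity thresholds.  Targets are specified as marginal risks —
  baseline 4.3% severe / 16.7% PPH; implementation-phase intervention 1.7% /
  8.5% — and converted to logit intercepts and treatment shifts by
  Gauss-Hermite matching of the marginal risk, so the generated marginal
  risk difference is exactly the nominal -2.6 pp (severe) and -8.2 pp (PPH).
  The effect applies only to intervention clusters in the implementation
  phase.
* **Blood loss.**  A three-stratum mixture (truncated lognormal < 500 ml;
  scaled Beta on 500-1,000; shifted lognormal above 1,000) so the severity
  strata match the thresholds exactly.
* **Deaths.**  Only among severe cases, at conditional rates 1.60%
  (treated) / 0.92% (untreated).  These are free parameters calibrated once
  so the per-arm DALY means and s.d.s match the published moments (~0.0077 /
  0.0116 means, ~0.39 / 0.45 s.d.); the near-constant per-birth death risk
  with a higher conditional rate under treatment reflects that averted
  severe cases are the milder ones.
* **Resource use.**  Generated per severity stratum: baseline stay
  (1 + Poisson days) and routine physician minutes for everyone; bundle
  drugs upon detection (detection probability 0.93 with the calibrated
  drape vs 0.25 under visual estimation — severe cases are always treated),
  so bundle administration is slightly *more* frequent in the intervention
  arm despite less PPH; escalation resources (transfusions, extra days, ICU,
  surgery, garments, tamponade, transfer, physician time) among severe
  cases, totalling ~36 USD expected excess per severe case; and a rare
  (0.68%) arm-independent obstetric-complication component (ICU-level care)
  that produces the documented heavy right skew (s.d. ~120 at mean ~43.5).
  A lognormal cluster-level resource-intensity multiplier (sd 0.10) adds
  between-cluster cost heterogeneity.  The severe-case excess was calibrated
  analytically so that the expected adjusted cost difference is +0.30 USD at
  the base drape price (1.25 USD 2023) and ~-0.00/-0.30/-0.60 USD at
  1.00/0.75/0.50 USD, reproducing the published sensitivity pattern.

What the generator does **not** emulate: the baseline-phase cost/DALY
imbalance between arms seen in the real trial (generation is arm-symmetric,
so unadjusted and adjusted differences coincide in expectation); real
correlation between a patient's blood loss and her specific resource items
beyond the severity stratum; country-specific event rates; seasonal drift.
Passing tests therefore demonstrate estimator correctness and calibration
under the design's statistical structure, not agreement with the actual
trial data, which are not public.

## Problem sizes and numerical choices

Validation runs use: 100 replicate trials of 40 clusters x 250
births/cluster/phase for risk-difference recovery and CI coverage (band
90-98%); 200 null-effect trials (18 clusters, 100/cluster/phase, 200
permutations) for permutation coverage; an 8-cluster fixture where
enumeration over all 36 within-stratum assignments is compared with the
reported p-value exactly; and one full-scale (78-cluster, ~210k births) run
with 200 permutations/bootstrap replicates for the qualitative
cost-effectiveness conclusion.  These sizes keep each check to seconds or a
few minutes while leaving Monte-Carlo error well inside the asserted bands.
Determinism: every stochastic routine takes an explicit seed; the pipeline
spawns per-stage seeds from one master seed via `SeedSequence`, and repeated
runs are bit-identical.

## Known limitations

* Laplace (nAGQ = 1) likelihood for the binomial GLMM; adequate for
  cluster-sized groups but not exact for small clusters with extreme rates.
* The robust covariance uses per-cluster profile scores and ignores the
  variance-component dependence of the Laplace log-determinant; the G/(G-p)
  scaling is a pragmatic small-sample fix, not an exact CR2/Satterthwaite
  treatment.
* Permutation inference re-randomizes within country strata only; the
  original allocation used minimization on additional covariates.
* No patient/societal costs, no implementation-strategy costing, no
  equity-weighted analysis, no EVPI — all outside the evaluation's scope.
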