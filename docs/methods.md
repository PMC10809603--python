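# Methods

## The problem and the estimand

Place-based summaries of neighborhood characteristics are usually
outcome-agnostic: a first principal component or an average of standardized
items (a *disadvantage score*, D-score). When a specific health outcome is of
interest — here the motivating example is HIV viral non-suppression (viral
load ≥ 400 copies) among people living with HIV in a city of ~200 census
tracts — an *outcome-oriented* summary can capture exactly the aspects of
place that predict that outcome. The **V-score** of a place is the
model-predicted probability of the outcome given the place's measured
characteristics, fitted flexibly,

    V = β(X₁, …, X_k),

standardized within calendar year to mean 0 and variance 1. The V-score is a
function of place variables only: two places with identical X share a V-score
regardless of their realized outcomes.

The estimation data are (a) a tract × year panel of k place variables — crime
and policing event rates per 1000 residents (skewed, zero-inflated), and
housing/economic proportions in [0, 1], some variables missing for whole
years — and (b) a longitudinal cohort of persons with visit-level binary
outcomes, where persons are followed for 1–17 visits, move between tracts,
and are replenished over time. Four clustering/imbalance problems follow, and
the pipeline addresses each one explicitly.

## The cluster-aware honest random forest

The regression model is a probability forest for the binary outcome on the
place variables plus calendar year, built for clustered panel data:

* **Cluster subsampling.** Each tree draws ⌈s·C⌉ of the C clusters (tracts)
  without replacement (s = `sample_fraction`, default 0.7), then an equal
  number of rows per sampled cluster — by default the size of the smallest
  sampled cluster — so no tract dominates a tree. When s < 1 the cluster
  subsample is capped at C − 1 so that out-of-bag prediction remains defined
  for every cluster even when C is tiny.
* **Honesty** (default on). Each tree's subsample is split at random into a
  half that chooses splits and a disjoint half that populates leaf values
  (`honesty_fraction` 0.5). A leaf that receives no estimation rows inherits
  the value of its nearest populated ancestor.
* **Splits.** Candidate thresholds are midpoints between consecutive distinct
  values of `mtry` (default ⌈√p⌉) randomly chosen variables; the chosen split
  maximizes the weighted between-child criterion
  W_L·W_R/(W_L+W_R)·(μ_L − μ_R)². Ties break deterministically: lowest
  variable index, then smallest threshold, then missing-left. Recursion stops
  at `min_node_size` (default 5) per child.
* **Missing covariates** are not imputed. Each split learns which side to
  send missing values by evaluating both directions (missingness incorporated
  in attributes). This preserves whole-year gaps in a variable as information
  the trees can use or route around, which matters for the adjacent-year
  proxy experiment below.
* **Prediction.** Out-of-sample prediction averages all trees' leaf values.
  Out-of-bag prediction for a training row averages only trees whose sampled
  cluster set excludes the row's cluster; rows whose cluster is in every tree
  are flagged missing rather than silently contaminated. Each tree runs on
  its own deterministic seed stream, so one tree's data-dependent number of
  random draws cannot alter another tree's randomness — this is what makes
  OOB predictions exactly invariant to a cluster's own outcome values.
* **Variable importance** is depth-decayed split frequency: a split on
  variable v at depth d ≤ 4 contributes d⁻², normalized to sum to 1. This is
  a convention choice; no importance metric is canonical for honest forests.
* **No automated tuning.** Parameters are exposed in configuration only;
  forest defaults are used everywhere, with honesty on and sampling fraction
  0.7.

Binary outcomes are treated as regression on {0, 1}; every leaf value is a
weighted outcome mean, so predictions are probabilities by construction.

## The five-step estimation pipeline

1. **Downweighting.** Within each (tract, year) cell, a person observed v
   times has each row's weight multiplied by 1/v, capping each person at
   total weight 1 per cell.
2. **Rough balancing.** Each repetition samples, per person, at most 3 years
   (uniformly without replacement) and one tract per kept person-year (with
   probability proportional to the person's downweighted weight in each
   tract-cell). With the default semiannual 1–17-visit structure this retains
   ≈30% of the naive sample size while keeping most persons.
3. **Connectivity-aware LOO.** For each tract T with cohort presence, a
   forest is fitted to the balanced sample minus T's rows minus *all* rows of
   persons ever observed in T (connectivity is computed from the full
   downweighted cohort, not the per-repetition sample, so the exclusion is
   unconditional). T's predictions for every panel year are out-of-sample
   predictions from that forest. Tracts with no cohort presence are predicted
   by one forest fitted to the whole balanced sample. The resulting leakage
   guarantee is exact: the LOO predictions for T are bit-identical under
   arbitrary modification of the outcomes of T's rows and of T-connected
   persons' rows elsewhere, holding seeds fixed.
4. **Repetitions.** Steps 2–3 are repeated (default 10; study-scale tests use
   2–3) with seeds derived deterministically from (master seed, repetition
   index), and per-tract forest seeds from (repetition seed, CRC32 of the
   tract id); the final prediction per cell is the mean over repetitions.
   Repetitions share no mutable state, so the average is order-invariant.
5. **Standardization.** Predictions are standardized within year over all
   tracts with predictions (both provenances), using the sample standard
   deviation (n−1). This removes year-level trends exactly:
   standardize(a + b·p) = standardize(p) for b > 0. The **generic** V-score
   is the per-tract mean of yearly scores, re-standardized to mean 0,
   variance 1.

**Proxy evaluation.** When a variable is missing for one year but available
in an adjacent year, the pipeline can be run twice — base versus a panel with
the adjacent-year values copied in — comparing the weighted Brier score of
each repetition's cell predictions against its balanced-sample outcomes,
pooled over repetitions. The proxy is adopted only on strict improvement;
ties revert (conservative).

## The D-score baseline

The comparison score is the first principal component of the standardized
place variables, fitted pooling all years (one loading vector, so scores are
comparable across years), missing entries mean-imputed — deliberately *not*
given the forest's missingness machinery. The sign is oriented so the score
correlates positively with the mean of standardized deprivation-group
variables, and scores are centered within year to put them on the same
detrended footing as V-scores.

## The synthetic data generator

The generator defines the study conditions for every test. It emulates:

* **Panel** (defaults: 200 tracts × 8 years, 7 rate + 12 proportion
  variables in three thematic blocks): per-block tract-level latent factors
  follow a stationary AR(1) across years with coefficient φ (default 0.8);
  variables load on their block factor with weight √ρ (ρ = 0.6 default
  within-block correlation). Rates are zero-inflated lognormal (π₀ = 0.3
  default zero mass); proportions are logit-normal. Whole-year availability
  gaps can be injected per variable.
* **Cohort** (default 464 persons): visit counts uniform on {1, …, 17}
  (matching the motivating cohort's printed support and ≈8.4 mean), two
  semiannual visits per observed year, entry year uniform over feasible
  windows, and first-order Markov mobility (default m = 0.1) to a uniformly
  chosen other tract between observed years. This structure reproduces the
  ≈30% retention under rough balancing arithmetically:
  Σ min(3, ⌈v/2⌉) / Σ v ≈ 0.29 for v uniform on 1–17.
* **Outcome model**: logit p = α_t + f(X) + u_person, with year intercepts
  declining linearly on the logit scale from logit(0.531) to logit(0.217)
  (the shape of the motivating cohort's prevalence decline, not a
  reproduction target), person effects u ~ N(0, 0.5²), and a selectable
  vulnerability function f standardized to a chosen effect size (default 1
  on the logit scale): *linear* (mean of standardized variables),
  *threshold* (indicator that one housing variable exceeds its 75th
  percentile — deliberately off the panel's first principal direction), or
  *interaction* (product of one rate and one housing variable). Outcome
  uniforms are drawn as a single block after all structural draws, so runs
  differing only in α_t are maximally coupled under a shared seed.
* **Truth**: f, α_t and the person-marginal cell probability
  E_u[expit(α_t + f + u)] (41-node Gauss–Hermite quadrature) on the full
  grid; `truth_vscore` standardizes these exactly as the estimator does,
  giving the recovery target.

What the generator does **not** emulate: real indicator marginals
variable-by-variable, recruitment waves beyond entry-time replenishment,
spatial adjacency (deliberately — the method uses no spatial features), or
informative mobility/dropout. Passing tests therefore demonstrate the
procedure's contracts and its recovery behavior under these conditions, not
calibration to any real city's data.

## Numerical and design choices

* Sample SD (n−1) everywhere a standardization is specified; declared for
  determinism, either convention is defensible.
* A split must strictly exceed criterion 1e-12, so constant-outcome nodes
  (criterion equal to float noise, ~1e-30) become leaves and a
  constant-outcome forest predicts the constant exactly.
* Generic scores with zero cross-year variance (an adversarial degenerate)
  are flagged missing with a warning rather than raised, as are tracts with
  no yearly scores; zero within-year variance of predictions is a hard error
  because the year-specific score is undefined.
* Orphan cohort rows (tract absent from the panel) are excluded with a
  logged count; real linkage is imperfect and erroring would be hostile.
* Tree kernels are numba-compiled; all randomness flows from integer seeds
  (forest seeds, repetition seeds, generator seeds), so every artifact of a
  run is bit-reproducible from the manifest.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full procedure at
study-shaped but desk-sized scales: 200 tracts × 8 years × 500 persons with
200 trees and 3 repetitions for parameter recovery; 100 tracts for the
comparative, detrending and persistence experiments; 20 tracts for the
leakage contract. These sizes were chosen so each experiment has enough
tracts for stable rank correlations while a full suite run stays in the
minutes range on one CPU.

## Known limitations

* With very small effective cluster sizes (smallest-sampled-cluster row
  sampling), trees are shallow and predictions are strongly shrunk toward
  the pooled mean; year-specific *levels* of predicted probability are
  attenuated even when the cross-tract *ranking* (all that the V-score
  retains after standardization) is recovered well.
* The depth-decayed split-frequency importance favors variables usable near
  the root; it is a diagnostic, not an effect size.
* `proxy_evaluate` doubles the full pipeline cost and its Brier comparison
  inherits repetition noise; at small scales ties and reversals are common
  (the conservative tie-break reverts).
* The generic score assumes yearly scores are exchangeable summaries of a
  persistent trait; under weak persistence (small φ) it averages away real
  year-to-year signal.
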