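# Methods

## The estimation problem

Nutrition surveillance needs the prevalence of acute malnutrition among
children under five — by case definition MUAC < 125 mm (GAM) or
< 115 mm (SAM) — from surveys that are expensive to field at classic
sizes (hundreds of children in ≥ 25 clusters). MUAC is approximately
normal in these populations, and a normal distribution's mass below a
cutoff is determined by its mean and SD alone. The PROBIT estimators
exploit this: p = Φ((c − μ)/σ). Estimating a mean needs far fewer
observations than estimating a small tail proportion, so the approach
trades a distributional assumption for sample size.

## Estimators

**Classic.** p̂ is the sample proportion below c. For clustered samples
the SE is the Taylor-linearised ratio form over cluster totals,
SE² = k/(k−1) · Σ_j (y_j − p̂ m_j)² / (Σ_j m_j)², with y_j cases and m_j
children in cluster j; for equal cluster sizes this reduces exactly to
the between-cluster variance of cluster proportions,
SE² = Σ_j (p_j − p̄)² / (k(k−1)). Simple random samples use
√(p̂(1−p̂)/n). The CI is Wald (p̂ ± 1.96·SE) truncated to [0, 1]; no
continuity correction or exact interval, since the method being
evaluated is the plain cluster-adjusted proportion. Degenerate
consequences at small n·p — zero-width [0, 0] intervals when no cases
are drawn — are left as-is; they are the phenomenon the evaluation
measures.

**PROBIT Method I** uses the sample mean with an SD from a regional
reference of prior surveys (below). **Method II** uses the sample's own
mean and n−1 SD. A sample with zero MUAC variance raises an error rather
than returning 0/1 prevalence: a surveillance user must see that
failure, not a confident extreme estimate.

**Confidence intervals (both PROBIT methods).** 2000 bootstrap
replicates (configurable) resample whole clusters with replacement —
the same number of clusters, each contributing all its records; simple
random samples resample records. Each replicate pairs its mean with an
SD per method: Method II recomputes the replicate SD; Method I draws one
SD from the region's empirical reference distribution, so SD uncertainty
from the prior corpus propagates into the interval. The replicate
z-scores z_b = (c − x̄_b)/σ_b give se_z = SD(z_b), and the CI is
Φ(ẑ ± z₀.₉₇₅ · se_z) with ẑ the point-estimate z-score — a
normal-theory interval on the z scale back-transformed through Φ, not a
percentile interval. One replicate stream of paired (mean, SD) draws is
used, since a single "SE from the bootstrap distribution" of z is what
the interval construction needs. Replicates with zero SD are redrawn
and counted; more than 10% redraws aborts the estimate as degenerate.
No second-stage (within-cluster) resampling and no further design-effect
inflation is applied; CIs may accordingly be slightly narrow for heavily
clustered data — a known property of the method as specified, not a
target of correction here.

## The regional SD reference

Prior surveys contribute their MUAC SD with weight equal to their
effective sample size ESS = n / DEFF, DEFF = 1 + (m̄ − 1)ρ̂, where m̄ is
the mean cluster size and ρ̂ the one-way ANOVA intraclass correlation
(negative estimates floored at 0; simple random surveys have DEFF 1).
Within each region, whole surveys are resampled with replacement, with
probability proportional to weight, 2000 times; the reference mean SD is
the mean over replications of the replicate-mean SD. The survey is the
resampling unit because the SD is a survey-level statistic. Whether the
weighting should enter the SDs themselves or the resampling
probabilities is not determinable from the method's description; both
give the ESS-weighted mean in expectation, and the weighted-resampling
reading is implemented. A built-in reference ships the five published
regional mean SDs (East Africa 12.3, West Africa 12.8, Central & South
Africa 13.0, Caribbean 12.8, Asia 12.0 mm); the empirical distributions
behind those means are not public, so each region defaults to a point
mass — with the consequence, stated rather than hidden, that Method I
intervals then carry no SD uncertainty — and an optional dispersion
(9 equally weighted normal-quantile atoms) can stand in for the missing
spread.

## Synthetic populations

The generator emulates the kind of survey corpus the estimators are
meant for: clustered populations (default 40 clusters × 20 children ≈
800, matching the ~815-children average of large multi-country survey
compilations) with MUAC = cluster effect + child residual, cluster
effects Normal(0, σ²ρ) and residuals carrying σ²(1−ρ), so the marginal
mean and SD equal the specified values exactly in expectation. Default
mean 135 mm and SD 12.5 mm put GAM near 21% and SAM near 5.5%; means of
120–148 mm span GAM from ~1% to ~50%. An optional skew-normal residual
(shape parameter; 0 = normal) is moment-corrected back to the target
mean and SD, for studying PROBIT bias under departure from normality.
What the generator does **not** emulate: real shape departures beyond
skewness (digit preference, heaping at integer mm, mixture structure),
unequal cluster sizes, PPS selection, seasonality and spatial structure.
Passing tests therefore certify the estimators' behaviour under the
normal-clustered model, not their field bias on non-normal MUAC.

## Sub-sampling design

From each source population, simulated surveys draw 25 clusters without
replacement and m = n/25 ∈ {1..8} children per cluster without
replacement, for n in {25, 50, …, 200}; simple random sources give
simple random sub-samples. Clusters holding fewer than m children
contribute all of them and the shortfall is topped up from additionally
drawn spare clusters, keeping n exact (the metrics grid requires exact
sizes); with the default generator, clusters always hold ≥ m children
and every sub-sample has exactly 25 cluster labels. Cluster selection is
equal-probability without replacement.

## Metrics

Per (method, cutoff, sample size) cell over all populations ×
replicates: **bias** = mean (and median) of estimate − truth in
percentage points, truth being each source population's empirical
proportion below the cutoff; **precision** = mean CI half-width
(upper − lower)/2 in percentage points, smaller is better; **coverage**
= share of closed CIs containing the truth. Classification at thresholds
5/10/15% GAM reports the sensitivity reading — among surveys whose true
GAM ≥ threshold, the share estimated ≥ threshold — together with
specificity and unconditional accuracy, since the conditional and
unconditional readings are both defensible and emitting all three makes
the ambiguity harmless. The bias regression is OLS of per-(population,
sample size, method) mean bias on dummy-coded region, GAM category
(<5, 5–9, 10–14, ≥15%), livelihood, residence, sample size, date period
and design, with treatment coding at the conventional reference levels
(East Africa, <5%, agriculture, rural, 25, before 2006, simple random);
the per-(population, size) unit is the finest granularity at which
sample size remains a meaningful predictor.

## Numerical and design choices

- Strict "<" at cutoffs: a child at exactly 125 mm is not a GAM case.
- Cleaning drops MUAC outside a configurable plausibility range, default
  80–220 mm (SMART-style fixed-range flagging); missing MUAC counts as
  excluded. Cleaning an already-clean dataset removes nothing.
- Proportions live in [0, 1] internally; reports print percentages to
  one decimal.
- All randomness flows from one master seed through named SeedSequence
  spawn keys — (0, i) population i, (1,) SD-reference bootstrap, (3, i)
  benchmark prior survey i, (i, j, r) study cell — so any cell re-runs
  identically in isolation and full runs are byte-reproducible.
- The study harness shares one replicate-moment stream per (sub-sample,
  PROBIT method) across cutoffs; methods get independent substreams so a
  failure in one cannot shift another's draws. Estimator failures are
  recorded as per-row error codes and the run continues.
- The standard benchmark (`muacprobit.benchmark`) uses 50 populations ×
  100 replicates × 8 sizes with 500 bootstrap replications — about two
  minutes on one core; 500 replicates leave bootstrap-SE noise an order
  of magnitude below the metric differences of interest, and the full
  2000 remains the estimator default.

## Known limitations

- Under the benchmark's conditions (true SAM ≈ 5.5%), PROBIT II's mean
  SAM half-width at n = 25 slightly exceeds the classic method's
  (≈ 7.5 vs 6.4 pp): at z ≈ −1.6 the replicate-SD variance term
  dominates se_z and the Φ-transform no longer compresses the interval
  below the binomial Wald width. At lower SAM prevalence (z ≲ −2) the
  PROBIT interval is tighter everywhere, and for GAM both PROBIT methods
  beat the classic method at every size.
- Wald small-count pathologies make classic SAM coverage at n = 25
  collapse (≈ 75% here, analytically 75.4% at p = 0.055; far lower
  still in corpora where SAM sits near 1–2%).
- Method I is only as good as its SD reference: a mis-matched regional
  SD shifts the estimate by roughly φ(z)·|Δσ|·|z|/σ per mm.
- No transformation or smoothing of MUAC toward normality is applied
  before the probit transform, and no incidence estimation is attempted.
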