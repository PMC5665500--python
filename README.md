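# muacprobit

Small-sample estimation of acute-malnutrition prevalence from mid-upper
arm circumference (MUAC), for nutrition-surveillance analysts and
epidemiologists who need prevalence estimates from far fewer children
than a classic SMART-style survey requires.

## The methods

A child is a case of global acute malnutrition (GAM) when MUAC < 125 mm,
and of severe acute malnutrition (SAM) when MUAC < 115 mm. Given a survey
sample of MUAC measurements, the package fits three estimators of the
population prevalence *p* below a cutoff *c*:

- **Classic** — the design-based proportion p̂ = #{MUAC < c}/n with a
  cluster-adjusted (Taylor-linearised ratio) standard error for two-stage
  cluster samples, binomial SE for simple random samples, and a Wald CI
  truncated to [0, 1].
- **PROBIT Method I** — treats MUAC as normal: p̂ = Φ((c − x̄)/σ̂) with x̄
  the sample mean and σ̂ an *external* SD taken from a regional reference
  of prior-survey MUAC SDs (weighted by effective sample size n/DEFF and
  bootstrap-averaged within region).
- **PROBIT Method II** — the same transform with both x̄ and the SD taken
  from the sample itself.

For both PROBIT methods the 95% CI is built on the z-scale: cluster
bootstrap replicates give z_b = (c − x̄_b)/σ_b, whose standard deviation
se_z yields the interval Φ(ẑ ± 1.96·se_z). Because the PROBIT methods use
the full continuous distribution instead of dichotomising each child,
they buy precision — the point of the approach is usable estimates at
sample sizes as small as 25–50.

The `simulate` / `evaluate` / `benchmark` modules reproduce the
Monte-Carlo evaluation design around these estimators: synthetic clustered
source populations, sub-sampling of 25 clusters × 1–8 children (sizes
25–200, 100 replicates each), and bias / precision (mean CI half-width) /
coverage / threshold-classification metrics, plus an OLS regression of
mean bias on survey characteristics.

## Worked example

```python
import numpy as np, muacprobit as mp

# a synthetic district population: 40 clusters x 20 children,
# mean MUAC 135 mm, SD 12.5 mm, intracluster correlation 0.05
pop = mp.generate_population(mp.PopulationSpec(survey_id="district-A", seed=3))
print(round(mp.true_prevalence(pop, 125), 4))      # 0.2137

# a small field survey: 25 clusters, 4 children each
sample = mp.subsample_clustered(pop, 100, rng=np.random.default_rng(0))
res = mp.ProbitPrevalenceII(sample).fit(cutoff_mm=125, n_boot=2000, seed=1)
print(res.summary())
```

```
Prevalence estimate (probit_II)
--------------------------------------------
cutoff               125.0 mm
n                      100
prevalence            19.4 %
95% CI            [ 13.4,  26.8] %
mean MUAC           135.58 mm
SD used              12.24 mm
bootstrap SE(z)     0.1248
```

The estimate (19.4%, CI 13.4–26.8%) brackets the true GAM prevalence of
21.4% from only 100 children. The classic estimator on the same sample
gives 20.0% with CI 13.1–26.9% — a slightly wider interval; the PROBIT
advantage grows as n shrinks. Method I works the same way from a regional
SD reference (`mp.builtin_reference()` ships regional mean MUAC SDs:
East Africa 12.3 mm, West Africa 12.8 mm, Central & South Africa 13.0 mm,
Caribbean 12.8 mm, Asia 12.0 mm).

A full study — populations → SD reference → sub-sampling grid → metrics —
runs from one config:

```sh
muacprobit run --config examples/run_config.yaml
muacprobit demo --out demo_out --seed 1     # small end-to-end run
```

writing `results.csv` (one row per simulated survey × method × cutoff),
`metrics.csv` (bias/precision/coverage per method × cutoff × size),
`classification.csv` and a reproducibility `manifest.json`.

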