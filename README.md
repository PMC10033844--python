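# phenomate

Individual-based quantitative-genetic simulation of **assortative mating by
reproductive timing** in a generalized semelparous salmonid life cycle.

Many aggregate breeders — Pacific salmon most prominently — mate
assortatively in time simply because an adult can only pair with whoever is
on the spawning grounds during its own residence window.  Most demographic
and eco-evolutionary models used in management assume random mating, which
can misstate recruitment and resilience when the real mating system is
phenological.  `phenomate` simulates discrete, non-overlapping generations
of individuals carrying two heritable phenological traits — **return day**
(the day within a 30-day spawning season an adult arrives) and
**reproductive lifespan, RLS** (how many days it survives on the grounds) —
and tracks census size (Nc), inbreeding effective size (Ne), and trait
evolution under stabilizing selection toward a fluctuating environmental
optimum.  It is aimed at quantitative and population geneticists who want a
mechanistic, parameterizable test bed for mating-system and
climate-variability scenarios.

## Model

Each generation, for every individual with trait vector **z** = (return
day, RLS) and the generation's optimum **θ** ~ N(**μ**, diag(σ²_θ)):

- **Fitness weight** (Gaussian stabilizing selection):
  `W(z) = exp(-½ (z-θ)ᵀ Ω⁻¹ (z-θ))`, where Ω shares the trait correlation ρ
  with the phenotypic covariance **P** and widens with the selection-width
  scalar ω (strength of selection = 1/ω).  Weights are then rescaled within
  the cohort onto [0, 1] (least-fit breeder → 0, fittest → 1).
- **Expected reproductive success**: `RS_exp = qpois(W, λ=2)` — the Poisson
  quantile map, under which a uniformly spread cohort has mean RS_exp = λ
  (a stable population).
- **Recruitment** is female-limited: next census = Σ RS_exp over females.
- **Parentage**: every offspring picks a (sire i, dam j) pair with
  probability ∝ `W_m(i)·W_f(j)·W_o(i,j)`, where W_m, W_f are relative
  RS_exp and W_o is a binary temporal-overlap gate — the mechanism of
  assortative mating.  Random-mating controls set all pair weights to 1.
- **Inheritance** is infinitesimal: offspring traits are drawn from a
  truncated bivariate normal centred on the mid-parent value with constant
  covariance **P**; return day is drawn first, RLS conditionally on it, and
  RLS can never exceed the season remaining after arrival.
- **Outputs**: full pedigree, per-generation Nc, sex-specific
  mean/variance-of-RS inbreeding Ne (combined as 4·Ne_m·Ne_f/(Ne_m+Ne_f)),
  trait means/variances, and replicate means with 95% CIs.

## Worked example

Run 100 replicate populations of 500 founders for 10 generations at the
standard parameter table (μ = (10, 5) days, σ² = (20, 20) days², ρ = −0.3,
ω = 2, σ²_θ = (20, 1) days², assortative mating):

```python
from phenomate import base_config, run_replicates, aggregate_iterations

cfg = base_config(iterations=100)
raw = run_replicates(cfg, master_seed=7)
agg = aggregate_iterations(raw)
print(agg[["generation", "nc_mean", "nc_lo", "nc_hi",
           "ne_nc_ratio_mean", "mean_return_day_mean", "mean_rls_mean"]]
      .round(2).to_string(index=False))
```

```
 generation  nc_mean  nc_lo   nc_hi  ne_nc_ratio_mean  mean_return_day_mean  mean_rls_mean
          0   500.00 500.00  500.00              0.65                 10.24           6.29
          1   621.76 596.99  646.53              0.63                 10.41           7.03
          5   842.24 754.56  929.92              0.61                 10.70           7.52
         10  1182.88 967.88 1397.88              0.62                 10.33           7.54
```

(middle rows elided).  Reading the output: the population grows modestly
under moderate selection; mean return day stays near the long-run optimum
of day 10; mean RLS climbs from its initial 5 days to ~7.5 during the
3–4-generation burn-in — the truncation of RLS at the end of the season
biases inheritance upward, a deliberate feature of the model — and Ne/Nc
settles near 0.6, reflecting the extra variance in reproductive success
that assortative mating and selection create relative to a Wright–Fisher
population (a randomly mating control gives Ne/Nc ≈ 1).

The same runs from a shell:

```bash
phenomate simulate --config my_config.yaml --seed 7 --out out/   # one scenario
phenomate experiment --name exp4 --seed 7 --out out_exp4/ --plot # an omega sweep
```

`simulate` writes `pedigree.tsv`, `summary_raw.csv`, `summary_agg.csv`,
`config_resolved.yaml` and a run log; `experiment` runs one of the four
preset sensitivity sweeps (exp1: return-day variance × mating system;
exp2: trait correlation ρ ∈ {−0.6, −0.3, 0}; exp3: environmental variance
σ²_θ ∈ {10, 20, 30}; exp4: selection width ω ∈ {1, 2, 3}).

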