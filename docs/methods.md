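# Methods

## Model structure

`phenomate` simulates a closed population with discrete, non-overlapping
generations, a 1:1 expected sex ratio, and two continuous phenological
traits per individual: return day r (arrival on the spawning grounds,
days 1..L−1 within a season of length L = 30 days) and reproductive
lifespan s (days survived after arrival, 1 ≤ s ≤ L − r).  One generational
step is, in order:

1. draw the generation's bivariate optimum θ;
2. assign each breeder an expected reproductive success RS_exp from its
   fitness weight;
3. set the next generation's census to the sum of female RS_exp;
4. assign every offspring a sire and dam by a weighted draw;
5. draw offspring traits around mid-parent values;
6. summarize the breeding cohort (census, Ne from realized RS, traits).

Iterations (replicate populations) are independent; a simulation is
100 iterations × 10 generations unless configured otherwise.

## Selection

The optimum θ = (θ_r, θ_s) is drawn fresh each generation from independent
normals centred on the initial trait means with interannual environmental
variances (σ²_θr, σ²_θs); default (20, 1) days².  The draw is untruncated —
an optimum outside the season is a bad year no individual can match.

The raw fitness weight is the Gaussian kernel
W(z) = exp(−½ (z−θ)ᵀ Ω⁻¹ (z−θ)).  Two constructions of the selection
surface Ω are provided (`omega_mode`):

- `variance_scaled` (default): Ω = ω·D·C·D with D = diag(σ_r, σ_s) and C
  the correlation matrix whose off-diagonal equals the phenotypic ρ — i.e.
  Ω = ω·P.  This is the calibration under which the simulator reproduces
  the published sensitivity trajectories.
- `sd_scaled`: Ω = ω²·P, the textbook reading of "width of ω phenotypic
  standard deviations".

The surface correlation can be decoupled from ρ via `omega_correlation`;
with it set to 0 the surface is axis-aligned.  We found that an
axis-aligned surface *reverses* the effect of ρ on population growth
(negatively correlated traits then escape, rather than suffer, the
between-trait constraint), so the ρ-matched surface is the default.

Raw weights are rescaled within each cohort (`fitness_scaling`):

- `cohort_minmax` (default): affine map of the cohort's weights onto
  [0, 1].  Under the Poisson-quantile map below this makes λ an exact
  stability point — a cohort whose rescaled weights are uniformly spread
  has mean RS_exp = λ — so demography is driven by the *shape* of the
  fitness distribution (how the cohort is arranged around the optimum),
  not by its absolute scale.  Caveat: on a nearly flat landscape the
  rescaling amplifies numerically tiny differences; use `none` when
  studying the no-selection limit.
- `none`: keep the raw kernel values.

Expected reproductive success (`rs_mode`):

- `poisson_quantile` (default, deterministic): RS_exp is the smallest k
  with Poisson(λ) CDF(k) ≥ w, with w capped at 1 − 10⁻⁹ to keep the
  quantile finite (the cap corresponds to RS_exp = 15 at λ = 2).
- `poisson_thinned`: RS_exp ~ Poisson(λ·w).  Note this mode bounds the
  expected per-female offspring number at λ·w ≤ λ, so with λ = 2 a
  population can at best replace itself; sustained growth requires the
  quantile mode.

λ defaults to 2 offspring per breeder at the weight midpoint.

## Mating and reproduction

Recruitment is female-limited: next census N' = Σ_f RS_exp(f).  Each of the
N' offspring independently draws a (sire i, dam j) with probability
∝ W_m(i)·W_f(j)·W_o(i,j), where W_m and W_f are RS_exp relative to the
whole-cohort mean and W_o ∈ {0, 1} is the temporal-overlap gate: pairs
whose presence intervals [r, r+s] intersect (touching endpoints count) get
1, disjoint pairs 0, regardless of overlap duration.  Sampling is with
replacement; there is no fecundity cap and no monogamy, so per-parent
realized RS_obs need not equal RS_exp.  Modes:

- `assortative`: gate active — mate choice by timing plus selection.
- `random`: gate forced to 1, selection weights retained.
- `random_uniform`: all pair weights 1 — fully neutral parentage.  This is
  the random-mating control used in the published comparison (it both
  declines demographically and gives Ne/Nc ≈ 1, the Wright–Fisher
  signature); `random` retains selection on parentage and instead grows
  with Ne/Nc ≈ 0.7.

If every pair weight is zero while recruits exist (e.g. no opposite-sex
overlap), the cohort fails to reproduce: the event is logged and the
lineage ends.  Remaining generations are recorded with census 0 so
replicate means include collapsed populations.  The functional-extinction
flag (census < 50) is bookkeeping only and never stops a run.

## Inheritance

Offspring traits follow the infinitesimal model: a truncated bivariate
normal centred on the mid-parent vector with the full, constant phenotypic
covariance P (no explicit G/R split — heritability is implicit in using P
as the segregation variance).  Sampling is sequential inverse-CDF: return
day from its truncated marginal N(mid_r, P₁₁) on [1, L−1], then RLS from
the conditional N(mid_s + (P₁₂/P₁₁)(r − mid_r), P₂₂ − P₁₂²/P₁₁) truncated
to [1, L − r].  Founders use the same scheme centred on the population
means.  Consequences worth knowing:

- the lower truncation at 1 day biases mean RLS upward; populations
  equilibrate near 7–8 days even though the optimum RLS is 5.  This
  mismatch is a real, deliberate feature of the model (maladaptation load
  created by the trait's hard bounds), not an artifact to correct;
- inverse-CDF truncation cannot reject-loop and keeps every draw inside
  the season window by construction, so runs are deterministic given the
  seed and no post-hoc clamping exists anywhere.

Return day is truncated to [1, L−1] rather than [1, L] so the RLS interval
[1, L−r] is never empty.

## Outputs and effective size

Per generation: census Nc, trait means and variances (n−1 denominator),
the realized θ, and the inbreeding effective size computed from realized
reproductive success within each sex,

    Ne_s = (N_s·k̄_s − 1) / (k̄_s − 1 + V_s/k̄_s),    Ne = 4·Ne_m·Ne_f / (Ne_m + Ne_f),

with k̄_s and V_s the mean and sample variance of RS_obs among all
potential breeders of sex s (zero-RS individuals included).  Ne from
generation t's RS_obs is attributed to generation t, and Ne/Nc divides by
that generation's census; the final generation therefore also performs a
reproduction step (its offspring are discarded) so its Ne is defined.  Ne
is reported missing when either sex is absent or produced no offspring.

Replicate aggregation reports, per generation and output, the mean across
iterations with a normal-approximation 95% CI (mean ± 1.96·SD/√n);
missing Ne values are excluded pairwise with the contributing count
reported.

## Seeds and reproducibility

Every replicate derives its generator from
`SeedSequence(master_seed, spawn_key=(level_index, iteration_index))`:
levels and iterations are independent, any subset can be re-run in
isolation, and identical spec + seed gives byte-identical tables.

## Default parameters

| Parameter | Default | Meaning |
|---|---|---|
| nc_initial | 500 | founder census |
| mu_return_day, mu_rls | 10, 5 days | initial trait means = long-run optima |
| var_return_day, var_rls | 20, 20 days² | phenotypic variances (constant) |
| rho | −0.3 | phenotypic correlation between traits |
| omega_scalar | 2 | selection width (strength = 1/ω) |
| var_theta_return_day, var_theta_rls | 20, 1 days² | interannual optimum variance |
| season_length | 30 days | spawning season |
| lambda_rs | 2 | Poisson rate of the RS map |
| generations, iterations | 10, 100 | run controls |
| extinction_threshold | 50 | functional-extinction flag |

The four preset experiments vary one axis each around this base:
return-day variance {10, 20, 30} × mating system (exp1), ρ {−0.6, −0.3, 0}
(exp2), σ²_θr {10, 20, 30} (exp3), ω {1, 2, 3} (exp4).

## Calibration notes and known limitations

The published description leaves three mechanics open: the exact
construction of Ω from the scalar ω, the meaning of the weight-scaling
factor, and which random-mating variant the control used.  We resolved
them by systematic comparison of every principled reading against the
published generation-10 outcomes: Ω = ω·P with cohort min–max scaling and
the fully uniform random control reproduces the selection-width sweep
(including near-extinction at ω = 1 and ~10× growth at ω = 3), the
environmental-variance direction, the random-vs-assortative contrast, and
the Ne/Nc levels.  Two quantitative discrepancies persist under every
variant we tested and are reported as such rather than tuned away: the
simulated effect of trait correlation on recruitment is weaker than
published (ρ = −0.6 populations decline less steeply), and growth under
very stable environments (σ²_θr = 10) is faster than published.  Users
comparing against those specific numbers should expect replicate means
within roughly 1.5× rather than within the published CIs.

Replicate means of census size are heavy-tailed (across-iteration SD is
comparable to the mean), so generation-10 means at 100 iterations carry
standard errors of ~10%; comparisons between nearby scenarios need the
paired directional tests, not point values.

Out of scope by design: age structure and overlapping generations, unequal
sex ratios, density dependence, harvest, dispersal, inbreeding depression,
explicit loci or large-effect genes, multi-modal fitness surfaces, and
trends in the mean optimum.
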