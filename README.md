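# socmort

Bayesian estimation of **age-specific adult mortality as a function of
time-varying social covariates** in wild primate cohorts — built for the
data problems that long-term field studies of dispersing species
actually have: birth dates known only to a bracket, observation that
starts at maturity or at immigration, right-censoring at the study
close, and males who disappear and may have either died or permanently
left the study population.

It is aimed at behavioural ecologists and biodemographers working with
longitudinal life-history plus interaction data (the motivating system
is the Amboseli yellow baboon population), and at methodologists who
want a tested reference implementation of survival trajectory analysis
with within-sampler covariate imputation.

## The model

With ages measured from maturity (x = age − α; α = 5 y for females,
7 y for males), mortality follows a Gompertz proportional-hazards model
with time-varying covariates:

    μ(x) = a·e^{bx}            a, b > 0
    h(x | w_x) = μ(x)·e^{κ·w_x}
    H(x | W) ≈ Σ_{t=0}^{x} μ(t)·e^{κ·w_t}      (1-year steps)
    S(x | W) = e^{−H(x | W)},   f(x | W) = h(x | w_x)·S(x | W)

The covariates w_t are the focal's **dyadic sociality index** with
female and male partners (DSI_F, DSI_M — grooming-based bond strength,
mean over the top three partners, z-scored within dyad type and
life-year) and **proportional dominance rank** (fraction of same-sex
groupmates dominated, from monthly win–loss matrices ordered by
minimising wins below the diagonal), all standardized by sex and age so
κ is a log hazard ratio per SD of deviation from age-typical values.
Males contribute DSI_F and rank only.

Disappeared males are handled by a latent Bernoulli out-migration state
with gamma-distributed departure ages (separate natal and immigrant
classes), whose priors are elicited from an agent-based dispersal
simulation.  Everything — parameters, latent states, uncertain birth
dates, missing covariates (truncated-normal draws from age-sex strata)
— is sampled jointly by Metropolis–Hastings within Gibbs; convergence
is monitored with the Gelman–Rubin R̂.

## Worked example

Simulate a cohort in the package's default regime (two sexes, male-only
dispersal, immigrant age brackets; true female effects −0.462 / −0.371 /
0.0 on DSI_F / DSI_M / rank), then fit the female model:

```python
from socmort import (SimConfig, simulate_population, records_from_frame,
                     AgeSexStandardizer, SocialMortalityModel)

cfg = SimConfig(n_females=800, n_males=800, seed=1)
individuals, covariates, truth = simulate_population(cfg)
records = records_from_frame(individuals)
std = AgeSexStandardizer().fit_transform(covariates)

model = SocialMortalityModel(sex="F", n_chains=3, n_iter=2000,
                             burn_in=500, seed=2).fit(records, std)
print(model.summary_[["parameter", "median", "lo95", "hi95",
                      "rhat", "hazard_effect_pct"]].round(3))
```

which prints (about 90 s on one core):

```
      parameter  median   lo95   hi95  rhat  hazard_effect_pct
              a   0.013  0.011  0.016 1.003                NaN
              b   0.101  0.088  0.114 1.003                NaN
    kappa_dsi_f  -0.376 -0.485 -0.278 1.004             31.329
    kappa_dsi_m  -0.254 -0.362 -0.155 1.001             22.466
kappa_prop_rank   0.028 -0.084  0.142 1.002             -2.834
```

Read: the Gompertz baseline is recovered (true a = 0.013, b = 0.10);
a +1 SD deviation in bond strength with females predicts a ~31%
reduction in the mortality hazard at any age (`hazard_effect_pct` is
100·(1 − e^κ) at the posterior median), bonds with males ~22%, and rank
shows no credible effect (its true κ is 0).  The κ estimates sit
slightly below their generative truths because observed covariates are
noisy, partially missing and re-standardized from the surviving sample
— the same dampening any field dataset imposes; see
[docs/methods.md](docs/methods.md).

The same workflow runs from the shell:

```bash
socmort simulate --out data/ --seed 1
socmort fit --data data/ --out run/ --seed 2
socmort diagnose --posterior run/posterior_F.csv
```

and from raw interaction records via `socmort metrics` (grooming,
agonism and effort CSVs → covariate table).

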