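# Methods

## The model

`socmort` estimates age-specific adult mortality in a wild primate
cohort as a function of time-varying social covariates, under age
uncertainty, right-censoring and (for males) permanent dispersal out of
the study population.

All ages are measured from maturity, x = age − α, with α = 5 years for
females (menarche) and 7 for males (first adult dominance rank).  The
baseline is the Gompertz law, μ(x) = a·e^{bx} (a, b > 0), which
describes adult primate mortality well.  Time-varying covariates act
proportionally on the hazard:

    h(x | w_x) = μ(x) · exp(κ · w_x)

where w_x collects the covariates in the focal's current life-year
(DSI_F, DSI_M and proportional dominance rank for females; DSI_F and
rank for males — adult males do not groom one another in this study
system) and κ is the vector of log hazard ratios per standard deviation.
The cumulative hazard is accumulated in discrete one-year steps, with
both μ and w evaluated at the left endpoint of each life-year and a
fractional final step for non-integer exit ages:

    H(x | W) = Σ_{t<⌊x⌋} h(t | w_t) + (x − ⌊x⌋) · h(⌊x⌋ | w_{⌊x⌋})

Survival is S = e^{−H} and the death density f(x|W) = h(x|w_x)·S(x|W),
with μ evaluated at the exact exit age and w at its life-year.  Every
likelihood contribution is left-truncated at study entry (divided by
S(x_entry)), so immigrants are conditioned on being alive when they
joined.

### Out-migration

Males may permanently leave the study population.  A Bernoulli state O
(probability γ_j) selects between death and departure, with separate
classes j for natal males (present at maturity) and immigrants (joined
after maturity).  Ages at departure (since maturity) are gamma
distributed per class.  By fate:

* observed death: log f(x_last) − log S(x_entry) + log(1 − γ_j)
* right-censored: log S(x_last) − log S(x_entry) + log(1 − γ_j)
* unknown fate, latent o = 0 (died): as a death dated at the last-seen
  age, plus log(1 − γ_j)
* unknown fate, o = 1 (departed): log γ_j + log g_j(x_last)
  + log S(x_last) − log S(x_entry)

The log(1 − γ_j) term for known-fate individuals applies to both origin
classes: anyone observed to die or survive in place demonstrably did
not leave, and without this term the immigrant departure probability
would be informed only by unknown-fate animals.  Dating o = 0 deaths at
the last-seen age is a convention; it biases the male baseline (a, b)
upward relative to a generative process in which unseen deaths occur
later, but leaves κ essentially untouched (checked by simulation; see
below).

The latent state has the conditional posterior

    P(o = 1) = γ g_j(x_last) S(x_last) / [γ g_j(x_last) S(x_last) + (1 − γ) f(x_last)]

and is re-drawn (Gibbs) every iteration.

### Priors

Mortality parameters carry vague priors: half-normal(1) for a,
half-normal(0.5) for b, Normal(0, 10) for each κ.  Out-migration priors
are elicited from a small agent-based dispersal simulation: agents
disperse at ages resampled from empirical dispersal-age samples and
choose a destination uniformly among study and non-study groups; the
fraction landing outside the study population becomes Beta
pseudo-counts for γ_j (prior strength 10 by default), and the ages of
the leavers are moment-matched to a gamma whose shape and rate become
centres of wide truncated-normal priors (sd equal to the centre).  The
simulator is a minimal stand-in mechanism: uniform destination choice,
no competition or scheduling, labelled as such.

## Covariate construction

**DSI.** Grooming events are pooled within dyad (direction ignored) and
binned by the focal's life-year.  Dyad-year rates are events divided by
an observation-effort denominator (co-residency time, supplied as an
input table), then divided by the mean rate of same-type dyads
(female–female vs female–male) in the same life-year, so the
population-mean dyad scores 1.  Rates are z-scored within (dyad type,
life-year) using the sample (n−1) standard deviation; degenerate strata
map to 0.  A focal's DSI_F (DSI_M) for a life-year is the mean z over
the top three female (male) partners, the mean of fewer if fewer exist,
missing if none.  The effort operationalisation is deliberately
isolated behind `compute_dyadic_rates` so a different observer-effort
correction can be swapped in.

**Rank.** Decided same-sex agonistic interactions are compiled into
monthly win matrices per group; matrix membership is the set of
same-sex adults that interacted in that month (the registry carries no
group-membership intervals, so presence is inferred from the records
themselves).  Ordinal ranks minimise total wins below the diagonal —
exhaustively for n ≤ 8, by best-improvement pairwise-swap descent seeded
from the previous month (or wins-minus-losses order) for larger groups,
never returning a worse objective than its start.  Ties prefer minimal
displacement from the previous month, then lexicographic ids.
Proportional rank is (n − r)/(n − 1), 1 = top, missing for singleton
groups; life-year rank is the mean of the available monthly values.

**Age–sex standardization.** Covariates are z-scored within (sex,
covariate, life-year) strata using the population (n) standard
deviation, so values are deviations from sex- and age-typical levels.
Integer life-year classes are used.  Strata with fewer than two
observations or zero variance standardize to 0 with a warning.

## The sampler

Metropolis-Hastings within Gibbs; per iteration, in fixed order:

1. stratified moments (mean, sd, min, max, count) of the observed
   standardized covariates, re-binned under the current imputed births
   (nearest-whole-year index shift);
2. truncated-normal imputation of every missing covariate cell from its
   stratum's moments; strata with fewer than two observations — and any
   cell beyond the oldest observed age — fall back to moments pooled
   across ages within sex.  Draws never leave the stratum [min, max];
3. Gibbs update of the latent out-migration indicators;
4. Metropolis update of uncertain births with uniform independence
   proposals inside the bracket.  The acceptance ratio recomputes ages,
   exposure and the re-binned observed covariates exactly; imputed cells
   keep their current draws within the step (they are redrawn at the
   next iteration), a standard within-Gibbs simplification;
5. random-walk Metropolis updates of a, b (log scale, with Jacobian),
   each κ component, γ_j (logit scale), and the gamma shape/rate
   parameters (log scale), plus one joint mean-preserving scale move per
   class along the shape–rate ridge, which that pair's strong posterior
   correlation otherwise makes slow to traverse.

Proposal scales adapt by Robbins–Monro recursion toward ≈0.3 acceptance
during burn-in only and are frozen afterwards, so the retained chain
satisfies detailed balance.  The default schedule is 8 chains × 5000
iterations with 1000 burn-in and no thinning; per-chain seeds derive
deterministically from the run seed, making output byte-reproducible.
Convergence uses the classic (non-split) Gelman–Rubin R̂,
√(((n−1)/n·W + B/n)/W); a split-half variant is available.  Summaries
report the median, central 68% and 95% intervals (linear-interpolation
quantiles), R̂, and for each κ the hazard-effect translation
100·(1 − e^κ) (percent hazard change per +1 SD).

The alternate imputation mode fills gaps once at preparation time by
linear interpolation along life-years (leading/trailing gaps take the
nearest observed value) and then treats the filled values as data.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes: 265
females and 277 males by default, α = 5/7, a 35-year observation
window, 58.5% of males immigrating at gamma-distributed ages after
maturity, immigrant birth brackets 2 years wide (12.5% of females carry
1-year brackets), male-only out-migration, right-censoring at the study
close, and covariates missing before an immigrant's entry plus 10%
missingness at random.

Covariate paths are a deterministic age profile (rising to a peak three
life-years after maturity, then declining) plus an AR(1) deviation
(ρ = 0.6, innovation sd 0.5); the rank column is squashed through a
logistic link so proportional ranks live in [0, 1].  Hazards act on the
cohort-standardized paths, so the generator and the preparation stage
share one covariate scale.  Lifespans invert the model's own
discrete-step cumulative hazard (constant hazard within each life-year),
guaranteeing simulator/likelihood consistency; immigrant deaths are
conditioned on survival to entry, and immigrant departure ages are
redrawn until they exceed the entry age (the inference likelihood uses
the untruncated gamma, a deliberate, documented mismatch that is
negligible when departures cluster after entry).

Defaults were chosen once to land the fate composition near the
published cohort: baseline (a, b) = (0.013, 0.10) for females and
(0.0055, 0.13) for males, departure probabilities (0.40, 0.25) for
natal/immigrant males, and a 0.6 probability that a male death is
observed — an unobserved death becomes a disappearance with unknown
fate, which is what makes the unknown class a genuine death/dispersal
mixture for the latent state to resolve.  This yields roughly 50/50
female death/censoring and an 18/40/42 male death/censored/unknown
split.  True κ defaults sit in the published-effect regime: (−0.462,
−0.371, 0) for females and (−0.33, +0.122) for males, i.e. hazard
changes of −37%/−31%/0 and −28%/+13% per SD.

An interaction-level generator emits grooming, agonism and effort
tables consistent with the latent state (Poisson grooming counts with
log-rate increasing in the two members' latent bonds; Bernoulli contest
outcomes favouring the higher latent rank with configurable steepness),
so the metrics stage can be exercised end to end.

**What the synthetic data do not emulate:** group fission/fusion,
seasonal environments, fertility, observer heterogeneity beyond a
scalar effort, and correlation between covariates and the decision to
disperse.  Passing recovery tests therefore demonstrate correctness of
the estimation machinery under the model's own assumptions, not
robustness to real-data violations of them.

## Problem sizes and numerical choices

Recovery studies run at 800 individuals per sex with 3 chains × 2000
iterations (burn-in 500); at that size the posterior sd of κ_DSIF is
0.05–0.07, the posterior median falls within 3 posterior sds of truth
with the correct sign, and all R̂ < 1.05.  Fitting the exact latent
covariates across replicate seeds shows the female estimator is
unbiased; the male κ are mildly attenuated (κ_DSIF ≈ −0.29 for a true
−0.33, rank ≈ +0.04 for a true +0.12) by the latent death/dispersal
mixture: with ~42% of males of unknown fate, part of the death signal
is probabilistically reassigned to the dispersal branch.  With
realistic measurement — covariates standardized from the surviving
observed sample, 10% missingness imputed within the sampler, brackets
misaligning life-year bins — the recovered hazard effects dampen
further (at n = 800, roughly 31%/22% for the female DSI effects whose
generative values are 37%/31%, and 16%/7% for the male effects of
28%/13%).  This attenuation is a property of the analysis under the
stated conditions, shared by any application to field data, and is why
the synthetic-cohort checks assert interval coverage and sign rather
than point equality.  The male baseline (a, b) is likewise not asserted
against generator truth (see the death-dating convention above).
Out-migration state recovery uses 900 males with γ = 0.5, giving ≳300
unknown-fate animals, and a point-biserial correlation of ≈0.6 between
the posterior mean indicator and the true cause.  Smoke and determinism
tests use cohorts of 30–60 per sex and 2 × 200–250 iteration chains.

Degenerate inputs: zero-variance or singleton strata standardize and
impute to their mean; a singleton rank group yields a missing rank; an
all-missing trajectory is an error for linear interpolation and a
configuration error for truncated-normal imputation; hazard exponents
are clipped at e^50 to keep rejected proposals finite; birth proposals
that leave no observation window are rejected with log-likelihood −∞.

## Known limitations

* Only first departures are modelled per origin class; re-immigration
  and higher-order departures of the same animal are out of scope.
* The observer-effort correction is an explicit stand-in (co-residency
  effort × mean-normalisation), isolated behind one function.
* The birth-age step holds imputed covariate draws fixed within the
  step, and covariate strata are treated as data rather than re-derived
  inside the acceptance ratio; both are documented Metropolis-within-
  Gibbs simplifications.
* Classic R̂ (as cited for the method) can miss trend non-stationarity
  that split-R̂ detects; the split variant is available behind a flag.
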