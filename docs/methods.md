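# Methods

## Model

The package implements the individual state-space formulation of the
Cormack–Jolly–Seber (CJS) model.  Conditioning on each animal's first
capture at occasion e_i, the latent alive indicator X_{i,t} and the
detection indicator Y_{i,t} evolve as

    Y_{i,t}   | X_{i,t} ~ Bernoulli(X_{i,t} p_{i,t}),      t >= e_i,  p_{i,e_i} = 1
    X_{i,t+1} | X_{i,t} ~ Bernoulli(X_{i,t} phi_{i,t}),    t = e_i .. T-1

with absorbing death.  phi_{i,t} is *apparent* daily survival — permanent
emigration from the pond array is indistinguishable from death in a CJS
design, so phi is a lower bound on true survival.  Both parameters carry
logit-linear submodels:

    logit(phi_{i,t}) = b0 + b_sex * male_i + b_age * z(t - e_i) + b_wl * z(wing_i)
    logit(p_{i,t})   = c0 + c_sex * male_i

Sex enters as a male indicator (female = reference, never standardized);
age and wing length are z-scored.  "Age" is operationally *days since
marking*: true age is unknown for wild-caught adults, and time-on-study is
the standard surrogate.  Its z-scoring uses the mean/SD over all in-study
(i, t) cells of the marked population; wing length uses the per-individual
mean/SD.  Whether sex, age and wing length enter one joint model or
separate per-covariate fits is left to the caller — both are expressible
through `ModelSpec`; nothing in the package asserts one as canonical.

Priors are independent normals on every coefficient with mean 0 and
precision 0.01 (SD 10) — flat on the logit scale, the conventional
noninformative choice in BUGS/JAGS-style CJS code.

## Marginalized likelihood

Rather than sampling the latent X (as JAGS does), the likelihood is
marginalized in closed form with the chi recursion

    chi_{i,T} = 1
    chi_{i,t} = (1 - phi_{i,t}) + phi_{i,t} (1 - p_{i,t+1}) chi_{i,t+1}

where chi_{i,t} is the probability that an animal alive at occasion t is
never detected afterwards.  Each individual contributes

    prod_{t=e_i}^{l_i - 1} phi_{i,t} p_{i,t+1}^{y} (1-p_{i,t+1})^{1-y}  *  chi_{i,l_i}

with l_i its last detection.  The posterior over coefficients is identical
to the latent-state formulation, mixing is better (no data augmentation),
and the form is directly testable: the test suite checks, for every
capture history up to T = 8, that the recursion equals the log-sum-exp of
the complete-data likelihood over all admissible latent sequences
(tolerance 1e-10), plus an independent pure-python Bernoulli-product
oracle.  The complete-data form is retained in the API for the simulator
and the enumeration oracle.  Animals first marked on the final occasion
contribute a constant (chi = 1) and are flagged informationally by
`validate_history`.

Numerical notes: probabilities come from `scipy.special.expit` and are
never clipped; log(0) terms propagate to -inf only for genuinely
impossible histories (e.g. a gap under p = 1).  `logit` rejects inputs at
0 or 1 rather than returning infinities.

## Sampler

Adaptive *blocked* random-walk Metropolis on the full coefficient vector.
During burn-in the global step size follows a Robbins–Monro recursion
targeting ~30% acceptance, and the proposal covariance is refreshed every
100 iterations from the running empirical covariance of the chain history
(Haario-style, with a 1e-9 diagonal regularizer).  All adaptation freezes
at the end of burn-in, so the kept draws come from a fixed-kernel chain
satisfying detailed balance.  Chains start at the prior mean (all
coefficients 0); chain c uses seed base_seed + c, and a fixed
configuration is bit-reproducible.  A chain that accepts nothing over a
500-iteration window raises rather than silently returning a frozen chain.

The original chain settings of this study design — 3 chains × 10,000
iterations, 1,000 burn-in, thin 100, i.e. 90 kept draws per chain, 270
total — are available as `MCMCConfig.study_settings()`.  The default
configuration (3 × 50,000, burn-in 5,000, thin 10) keeps 4,500 draws per
chain for stabler quantile estimates; these are configuration values, not
separate code paths.  Correctness of the sampler is pinned by a dense-grid
oracle: for the intercept-only model the posterior mean and 95% CrI
endpoints must match a Laplace-centered 400×400 numerical integration of
the same posterior within 3 Monte-Carlo standard errors (MCSEs from
effective sample size, plus the grid's half-cell resolution — the oracle's
own discretization error).

Convergence is reported as the classic split-chain potential scale
reduction factor (each chain halved, R̂ = sqrt(((n-1)/n W + B/n)/W)).
This matches the R̂ convention of BUGS-era CJS reports; arviz's
rank-normalized R̂ is used only as an independent cross-check in the
tests.  Degenerate (constant) chains raise instead of reporting 1.

Posterior summaries are mean, SD and the equal-tailed 95% interval
(2.5%/97.5% quantiles); highest-density intervals are out of scope.
Derived quantities — in particular the **average resighting probability**
and **average survival probability** — are computed per draw and then
summarized.  Their definition is genuinely open (field reports rarely say
how "average p" is averaged); the default is the population average of
inv_logit over every individual's in-study linear-predictor cells, with an
intercept-at-reference-level variant (`kind="reference_level"`) also
provided.

## Synthetic data generator

`simulate` emulates a staggered-entry dual-channel survey: entry occasions
multinomial over occasions 1..T-1 (uniform by default), sex either
Bernoulli or fixed counts, wing length normal per sex (rounded to 0.01 mm,
the caliper's resolution), survival simulated forward from the same
logit-linear model the fitter uses, and — while alive, after entry — two
*conditionally independent* Bernoulli detection channels per day, merged
by union into the CV+HSV dataset.  The behavioral mechanism behind the
channels (CV catches perched/copulating animals, HSV catches fliers) is
summarized entirely by the two channel probabilities; that is sufficient
to reproduce the statistical structure the CJS analysis assumes.

`study_preset` fixes the two study populations: n = 107 (74 M / 33 F) and
n = 152 (96 M / 56 F), T = 39 daily occasions.  Channel probabilities were
chosen once from the published estimate scales: CV ≈ 0.05 for both
species; HSV set so the union detection is ≈ 0.19 (*A. junius*: female
0.040/0.110 per channel, male 0.056/0.162) or ≈ 0.06 (*R. multicolor*:
0.050/0.0105, no sex effect).  Survival intercepts and sex contrasts sit
near the published sex-specific estimates (A: F 0.928 / M 0.883;
B: F 0.831 / M 0.947, the published male value of 0.975 being moderated to
keep the preset away from the boundary).  Wing-length means (50/51 mm and
43.5/44.5 mm) are typical hind-wing lengths for these species.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: individual heterogeneity in detectability,
behavioral correlation between the channels (the field channels cover
*different* behaviors and rarely overlap, making them closer to mutually
exclusive than independent), weather-driven daily effort variation,
spatial pond structure, and dispersal as a distinct state.  A visible
consequence: simulating at the published *parameter* scales yields more
resighted individuals (and a different CV→merged increase) than the
published *counts*, which is expected — a homogeneous CJS at phi ≈ 0.9,
p ≈ 0.19 over 39 occasions implies a higher ever-resighted fraction than
the field data showed.  The published counts are therefore used directly
(as inputs) for the count-arithmetic checks, while the synthetic pipeline
checks internal consistency: parameter recovery, interval calibration and
the information gain from the second channel.

## Comparison layer

`fit_both` builds both histories from one record set, fits them with the
identical `ModelSpec` and chain settings (seeds offset by the chain count
and logged), and reports per-quantity credible-interval width ratios
CrI_CV / CrI_merged — above 1 means the video channel tightened the
interval.  `effect_report` emits a survival table shaped one row per
(sex × method) — method labels "HFR" ≡ CV+HSV and "No HFR" ≡ CV are written
together with the channel names — and posterior mean ± CrI survival curves
over the observed range of each continuous covariate (50-point grid by
default, reference sex, other covariates at their standardized zero).

## Problem sizes used in the checks

Likelihood enumeration: all histories for T ∈ {2, 3, 5, 8}.  Grid oracle:
n = 200, T = 15, 400×400 grid, 3 × 12,000 kept draws.  Interval
calibration: 20 replicates at n = 150, T = 39, phi = 0.88, p = 0.19
(4 coefficients; 95% CrIs must cover each truth in ≥ 80% of replicates —
the loose bound reflects the small replicate count).  The acceptance
script runs each species preset with 3 chains × 40,000 iterations
(burn-in 8,000, thin 16), which brings every split-R̂ below 1.01.

## Known limitations

- Time-varying detection (per-occasion p) and multi-state extensions are
  out of scope; p varies only with sex.
- Calendar dates are mapped to equally spaced occasion indices through a
  supplied survey-day list; gaps (bad-weather days) are not modeled.
- Missing wing length is a hard error by default (mean imputation is the
  caller's explicit choice), so fits never silently drop animals.
- Very sparse histories (low p, high phi) leave the survival intercept
  weakly identified; the sampler converges but CV-only intervals can span
  most of (0, 1) on the probability scale — which is, in fact, the
  phenomenon the dual-channel design addresses.
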