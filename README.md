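# resight

Bayesian Cormack–Jolly–Seber (CJS) analysis of **dual-channel mark-resight
data**: surveys where marked animals are re-encountered both by conventional
visual observation (CV, reading the mark with the naked eye) and by
high-speed video (HSV, reading the mark later from slowed-down footage).
The motivating system is daily capture–mark–recapture of large, rarely
perching dragonflies (*Anax junius*, *Rhionaeschna multicolor*) at an array
of experimental ponds, where naked-eye resighting rates are very low and a
supplementary video channel substantially raises them.

The package is for ecologists who want to quantify what an extra detection
channel buys: how many more individuals are ever resighted, how survival
and resighting estimates shift, and how much the 95% credible intervals
tighten.

## The model

For individual *i* first captured at occasion *e&#8321;*, with latent alive
state *X&#8321;,&#8348;* and detection *Y&#8321;,&#8348;* (t ≥ *e&#8321;*,
*p&#8321;,&#8337;&#8321; = 1*):

    Y[i,t]   | X[i,t] ~ Bernoulli( X[i,t] · p[i,t] )      observation
    X[i,t+1] | X[i,t] ~ Bernoulli( X[i,t] · φ[i,t] )      state (absorbing death)

φ is *apparent* daily survival (mortality and permanent emigration are
confounded); p is the daily resighting probability.  Both get logit-linear
submodels — survival may depend on sex, age (days since marking) and
hind-wing length; resighting on sex — with flat normal priors
N(0, sd = 10) on every coefficient.  Instead of sampling the latent states,
the likelihood is marginalized in closed form with the χ recursion
(χ<sub>i,t</sub> = probability an animal alive at *t* is never seen again),
and the posterior is sampled with an adaptive blocked random-walk
Metropolis sampler with split-R̂ convergence diagnostics.

Capture histories are built from long-format encounter records by
set-union over (individual, day): an animal seen by both CV and HSV on the
same day counts once, which is exactly the same-day redundancy rule used
in the field protocol.  `channels={CV}` yields the CV-only dataset,
`channels={CV, HSV}` the merged one.

## Worked example

Simulate a survey at the scale of the *A. junius* study population
(107 marked animals — 74 males, 33 females — over 39 daily occasions, CV
detection ≈ 0.05, merged detection ≈ 0.19), then fit both datasets:

```python
from resight import (study_preset, simulate, build_history, Channel,
                     resight_summary, fit_both, MCMCConfig)

scenario = study_preset("anax_junius", base_seed=7)
records, truth = simulate(scenario)

cv     = build_history(records, {Channel.CV}, scenario.T)
merged = build_history(records, {Channel.CV, Channel.HSV}, scenario.T)
print(resight_summary(cv, merged))

config = MCMCConfig(n_chains=3, n_iter=12_000, burn_in=2_000, thin=10, base_seed=7)
fit = fit_both(records, truth.covariates, scenario.spec, config, scenario.T)
print(fit.summary_merged.table.round(3))
```

which prints

```
ResightSummary(n_marked=107, n_resighted=32, pct_resighted=29.9,
               n_resighted_b=63, pct_resighted_b=58.9, pct_increase=96.9)
                    mean     sd    lci    uci   rhat
phi.intercept      2.816  0.324  2.255  3.530  1.000
phi.sex           -0.499  0.364 -1.269  0.163  1.000
p.intercept       -1.804  0.191 -2.186 -1.435  1.000
p.sex              0.420  0.228 -0.010  0.867  1.000
avg_survival_prob  0.919  0.011  0.896  0.939  1.000
avg_resight_prob   0.184  0.016  0.154  0.217  1.001
```

Reading this: adding the video channel roughly doubled the number of
individuals ever resighted (32 → 63).  On the merged dataset the daily
resighting probability is estimated at 0.184 (95% CrI 0.154–0.217, truth
0.189) and population-average daily survival at 0.919; coefficients are on
the logit scale with females as the reference sex, so `phi.sex = −0.50`
means males survive at lower daily odds.  `fit.ci_width_ratios` gives, per
quantity, the CV credible-interval width divided by the merged one — values
above 1 mean the video channel tightened the interval (here 12.6× for the
survival intercept, whose CV-only posterior is nearly unidentified).
All R̂ ≈ 1.00 indicates the three chains agree.

The same workflow is available from the shell:

```sh
resight simulate --species anax_junius --seed 7 --out-dir runs/sim
resight build    --encounters runs/sim/encounters.csv --T 39 --out-dir runs/build
resight compare  --encounters runs/sim/encounters.csv \
                 --covariates runs/sim/covariates.csv \
                 --T 39 --seed 7 --out-dir runs/cmp
```

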