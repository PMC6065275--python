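# fishmove

Prior-informed hidden Markov classification of demersal fish movement
behaviour from data-storage-tag (DST) records, and the scaling of decoded
individual behaviour to population-level patterns.

## The problem

Archival tags on free-roaming fish (Atlantic cod, European plaice) yield one
bivariate daily time series per fish: horizontal movement *h* (great-circle
step length between daily geolocation estimates, m/day) and vertical
movement *v* (daily sum of absolute 10-minute depth changes, m/day), both
natural-log transformed. Fitting a hidden Markov model per fish identifies
resident vs migrating behaviour, but tagging cohorts are dominated by short,
data-poor tracks on which a 12-parameter model will not converge — and
independently fitted models give no guarantee that "state 1" means the same
behaviour in two different fish.

`fishmove` implements a two-stage remedy: fit every fish unprimed, select
the data-rich fits, summarise their fitted state means into species-level
Gaussian priors, and refit the data-poor remainder with those priors
anchoring state identity. The result is one usable, label-consistent state
sequence per fish, which makes population-level questions (seasonal timing,
state-dependent space use, substock movement rates) answerable directly.

## The model

Each fish's daily observation x_t = (h_t, v_t) follows a 2-state HMM with
states R (resident: low movement rates) and M (migrating: high rates):

- latent first-order Markov chain S_1..S_T with transition matrix
  Γ = [[γ_RR, 1−γ_RR], [1−γ_MM, γ_MM]], uniform initial distribution ω;
- state-conditional emissions x_t | S_t = j ~ MVN(μ_j, Σ_j), where
  μ_j = (μ_jH, μ_jV) and Σ_j is the full 2×2 covariance (σ_jH, σ_jV, ρ_j);
- 12 free parameters per fish, estimated by maximum a posteriori: the
  forward-algorithm likelihood times
  - Beta(α=99, β=1) priors on γ_RR and γ_MM — prior mean 0.99, i.e. an
    expected dwell of 1/(1−0.99) = 100 days, so states track seasonal shifts
    rather than day-to-day noise; and
  - (stage 2 only) Gaussian priors N(m_jd, δ_jd) on the four state means,
    with m and δ the across-fish mean and variance of the data-rich fits'
    μ̂_jd (4 priors per species; δ is a variance).

Decoding is forward–backward smoothing followed by per-day argmax; a day is
flagged uncertain when the winning smoothed probability is below 0.85.
Dwell times in each state are geometric by construction, which the
`dwell_time_analysis` diagnostic verifies on decoded sequences.

## Worked example

```python
import numpy as np
from fishmove import (SpeciesSpec, TransitionPrior, FitConfig,
                      simulate_individual, fit_map)

fish = simulate_individual(SpeciesSpec.cod(), 200, seed=4, fish_id="cod_demo")
fit = fit_map(fish.path, TransitionPrior(), None, FitConfig(n_restarts=6, seed=0))

print("converged:", fit.converged)
print("gamma_RR=%.3f gamma_MM=%.3f" % (fit.params.gamma_rr, fit.params.gamma_mm))
print("mu (log m/day):"); print(np.round(fit.params.mu, 3))
print("resident days: %d  migrating days: %d"
      % ((fit.states == 0).sum(), (fit.states == 1).sum()))
print("uncertain days (<0.85):", int(fit.uncertain.sum()))
print("resident horizontal rate: %.1f km/day"
      % (np.exp(fish.path.h[fit.states == 0]).mean() / 1000))
print("migrating horizontal rate: %.1f km/day"
      % (np.exp(fish.path.h[fit.states == 1]).mean() / 1000))
print("decoding accuracy vs truth: %.3f" % (fit.states == fish.states).mean())
```

prints

```
converged: True
gamma_RR=0.999 gamma_MM=0.996
mu (log m/day):
[[9.082 3.645]
 [9.76  5.132]]
resident days: 39  migrating days: 161
uncertain days (<0.85): 0
resident horizontal rate: 9.9 km/day
migrating horizontal rate: 20.8 km/day
decoding accuracy vs truth: 1.000
```

The fitted state means are on the log scale: row 1 is resident
(exp(9.08) ≈ 8.8 km/day horizontal, exp(3.65) ≈ 38 m/day vertical), row 2
migrating (≈ 17 km/day, ≈ 169 m/day). The high self-transitions reflect the
persistence prior; every day is decoded with smoothed probability ≥ 0.85,
and the decoded sequence matches the simulation truth exactly.

## Command-line pipeline

The whole workflow — simulate (or read) raw records, preprocess, two-stage
fit, decode, population summaries, prior-sensitivity reruns — runs from one
YAML config:

```
fishmove all --config run.yaml --verbose
```

Stages (`simulate`, `preprocess`, `fit`, `classify`, `population`,
`sensitivity`) are individually re-runnable from the previous stage's
on-disk artifacts; every output gets a manifest sidecar (config hash, seed,
version). See `fishmove --help`.

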