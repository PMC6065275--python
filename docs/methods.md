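# Methods

## Model

Each fish's movement path is a dated bivariate series x_t = (h_t, v_t),
t = 1..T, of natural-log daily horizontal and vertical movement (m/day). A
discrete 2-state hidden Markov model is assumed: a first-order Markov chain
S_t ∈ {R, M} with transition matrix Γ parameterised by the two
self-transitions (γ_RR, γ_MM), a uniform initial distribution ω (fixed,
never estimated), and state-conditional bivariate normal emissions
MVN(μ_j, Σ_j) with full covariance (σ_jH, σ_jV, ρ_j). Horizontal and
vertical movement are thus conditionally dependent given the state, which is
what lets a day with, say, low vertical but high horizontal activity be
resolved by the joint evidence. Twelve free parameters per fish.

The model is deliberately simple: no covariates on Γ, no hidden semi-Markov
dwell distributions, no third "intermediate activity" state. Dwell times are
geometric by construction; `dwell_time_analysis` tests decoded sequences
against that implication as a model check.

## Estimation

Parameters are estimated by maximising the log posterior: the forward
log-likelihood (scaled forward recursion; the backward pass for smoothing is
likewise normalised per step — both jitted with numba) plus

* `TransitionPrior`: independent Beta(α, β) densities on γ_RR and γ_MM.
  Default α=99, β=1: prior mean self-transition 0.99, expected dwell
  1/(1 − 0.99) = 100 days, encoding multi-month behavioural persistence.
* `MeanPriors` (stage 2 only): independent Gaussians N(m_jd, δ_jd) on the
  four state means. **δ is a variance**, not a standard deviation — the
  ±10% sensitivity scenarios scale δ itself.

Numerical choices:

* Optimiser: L-BFGS-B on an unconstrained transform — logit for γ, identity
  for μ, log for σ, Fisher-z for ρ — with box bounds (|logit γ| ≤ 7,
  log σ ≥ log 1e−3, |z| ≤ 5) to keep the objective finite.
* Restarts: the first start is deterministic (state means at the 25th/75th
  percentiles of h and v, σ at 0.75 × the marginal SD, ρ = 0, γ at the
  prior mean; with mean priors the means start at m). Remaining starts are
  jittered draws around it; `n_restarts` defaults to 10 and everything is
  deterministic given the config seed. Sensitivity refits additionally seed
  one restart with the baseline estimate to stabilise comparisons.
* Convergence/degeneracy: a fit is reported non-converged when no restart
  succeeds, when a state's expected occupancy (column sum of the smoothed
  probabilities) is below 2 days, or when any σ̂ sits on its lower bound
  (1e−3). Degenerate fits are still decoded — a data-poor fish that truly
  stayed in one state for its whole track gets a usable state sequence and
  an honest "don't trust the unused state's parameters" flag.
* Label identifiability: unprimed fits are relabelled after optimisation so
  that R has the smaller horizontal mean (resident = slow). Prior-anchored
  fits are not relabelled; their identity comes from the priors.

Decoding uses forward–backward smoothed probabilities with per-day argmax
(ties broken towards R); a day whose winning probability is below 0.85 is
flagged uncertain. One-step-ahead forecast pseudo-residuals (predictive
state mixture of marginal normal CDFs, probit-transformed) are provided per
dimension as a residual check.

## Preprocessing

* Vertical metric: sum of |Δdepth| over the 143 consecutive 10-minute pairs
  of a UTC day; only complete days (144 samples) qualify. An incomplete day
  anywhere inside the retained window disqualifies the fish (the complete-
  recording rule); days are not repaired or interpolated.
* Horizontal metric: haversine great-circle distance between consecutive
  daily positions on a sphere of radius 6,371 km. Steps are stamped to the
  earlier day so that day t's h and v describe the same 24 h; a calendar gap
  in the track produces no step for the earlier day.
* Trimming and filtering: the first 14 days and last day of the aligned
  series are dropped (release/recapture artefacts); fish with fewer than 40
  remaining days are rejected with a typed reason.
* Zero floor: raw rates below 1 m/day are raised to 1 m/day before the log
  transform. A literally zero movement day would otherwise map to −∞; 1
  m/day is orders of magnitude below either state's mean, so the floor only
  regularises, it does not move mass between states. Configurable.

## Two-stage classification

Stage 1 fits every fish with the transition prior only. Data-rich fits are
selected by `SelectionCriteria`: converged, T ≥ 150 days, and both states
occupying ≥ 10% of decoded days. These thresholds are this package's
reconstruction of "long and informative enough for stable unprimed
fitting"; all three are config-exposed. The selected fits' state means are
summarised per species into m (across-fish mean) and δ (across-fish
unbiased variance, floored at 1e−4), giving 4 Gaussian priors per species.
Stage 2 refits every non-selected fish with those priors multiplied into
the likelihood. Selected fish keep their stage-1 fits, so no fish is refit
with priors built partly from itself.

Label coherence — "resident means the same thing in every fish" — is
operationalised by `is_label_flipped`: a fish's fitted state means must
match the species prior's direct assignment better (in prior-standardised
squared distance) than the swapped assignment. This is the guarantee the
pipeline actually provides. The empirical day-mean ordering
(mean h | M > mean h | R) also holds pooled across a cohort and in the
overwhelming majority of individual fish, but at realistic movement scales
the horizontal separation between states (~0.4 log units) is comparable to
the sampling noise of a 5–15-day state mean, so occasional per-fish
inversions occur even under perfect decoding and are not treated as
failures; tests require ≥ 95% of testable fish (≥ 3 days in each state) to
satisfy the empirical ordering.

## Population summaries

* Week w = floor((day_of_year − 1)/7) + 1, capped at 52 (days 365/366 join
  week 52), pooling years. Weekly `mean_p_resident` averages the smoothed
  resident probability over all fish-days; the SE is the across-fish
  standard error of per-fish weekly means; `prop_resident` is the fraction
  of fish-days allocated to R.
* State-dominant windows: maximal runs of weeks with mean state probability
  strictly above 0.5, grouped and allowed to wrap week 52 → 1 (migration
  seasons span the new year).
* Utilization grids: state- and window-filtered fish-days binned into
  square cells, default 5 km × 5 km (the conventional reading of "5 km²
  cells"; the side length is one flag away). Positions are projected with a
  local Lambert azimuthal equal-area projection centred on the contributing
  days' centroid, keeping cell areas honest at North-Sea scale; the grid is
  unbounded, so no position is ever dropped. Cell counts conserve the
  number of matching fish-days exactly.
* Substock rates: per fish and state, the arithmetic mean of raw daily
  rates (exp of the log metrics) over days allocated to that state, then an
  unweighted mean across the substock's fish (horizontal reported in
  km/day). Raw classified observations are used rather than lognormal
  back-transforms of (μ̂, σ̂); the back-transform is available behind a flag.
* Dwell times: per-state run lengths pooled across fish; runs touching
  either series end are censored and excluded from the geometric fit
  (p̂ = 1/mean of uncensored runs, chi-square GOF with bins merged to
  expected counts ≥ 5 and one estimated parameter). Note that uncensored
  interior runs are length-biased short when T is comparable to the mean
  dwell — at a 100-day dwell, tracks of ~600 days understate the mean by
  ~20% while tracks of 3000 days are nearly unbiased — so the dwell
  diagnostic harness uses 12 tracks of T = 3000 (~350 pooled runs).

## Sensitivity analyses

Named scenarios rerun the fitting and report the mean percentage of days
whose label changed against the baseline decoding:

* `test1` Beta(49.5, 0.5): same 0.99 prior mean (100-day dwell), roughly
  double the prior variance. `test2` Beta(49, 1): prior mean 0.98, halving
  the expected dwell to 50 days. Applied to the data-rich fish.
* `testA` / `testB`: all δ scaled by 1.10 / 0.90 (m and the transition
  prior untouched), applied to the prior-dependent stage-2 fish.
* `univariate`: a horizontal-only normal emission model (6 parameters,
  same transition prior), quantifying what the vertical dimension adds.

## Synthetic cohorts

`simulate` generates Markov-switching bivariate lognormal daily movements
with per-fish parameter heterogeneity (Gaussian hyper-distributions on the
state means, redrawn until the resident horizontal mean is below the
migrating one; uniform ranges for σ and ρ; Beta(99,1) self-transitions
unless fixed), plus consistent raw records: a geolocation track whose daily
displacements are exactly exp(h_t) (uniform headings while resident,
correlated headings while migrating, mid-latitude tangent-plane dead
reckoning — the step-length computation recovers exp(h_t) to well under
0.1%), and a 10-minute depth series whose within-day increments sum exactly
to exp(v_t) (half-normal increments rescaled, signs chosen to respect the
0..seabed bounds). Default movement scales are anchored to published
state-dependent rates for North Sea cod and plaice (resident ≈ 6.5–9.2
km/day horizontal, tens of m/day vertical; migrating ≈ 13–14 km/day, low
hundreds m/day) — an emulation for plausibility, not a replication of any
dataset. Seasonal cohorts toggle between two transition matrices by
calendar week (default resident season weeks 23–43), the simplest mechanism
that produces annual state cycles.

What the generator does *not* emulate: oceanography (tides, temperature,
bathymetry-constrained movement), geolocation error, individual covariates
(length, sex, maturity), and any covariate-driven switching. Passing tests
therefore demonstrate the statistical machinery — recovery, rescue of
data-poor tracks, label consistency, seasonal-window detection — under the
model's own assumptions plus controlled heterogeneity, not robustness to
every field artefact.

## Harness sizes

The recovery harness uses 20 fish at T = 500 with cod-scale parameters; the
rescue harness a 34 data-rich (T 380–550, seasonal) / 73 data-poor
(T 40–80) two-species cohort mirroring a realistic tagging programme; the
sensitivity harness a well-separated seasonal cohort (8 rich / 6 poor).
Cohort fits use 5–6 restarts, enough that restart-to-restart variation is
not the binding error term at these track lengths.

## Known limitations

* The selection thresholds for data-rich fits are a reconstruction; other
  reasonable choices select different subsets (they are config knobs).
* Fitted Γ is homogeneous in time even for seasonally switching fish; the
  decoded states remain accurate because the emissions separate the states,
  but γ̂ should be read as a time-average.
* The Beta prior terms use the normalised pdf; with fixed (α, β) the
  normalising constant shifts the posterior by a constant and does not move
  the maximiser.
* Single-state fish (genuinely resident or migrating throughout) yield
  unidentifiable parameters for the unused state; they are decoded and
  flagged non-converged rather than dropped.
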