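# Methods

## Model

The package fits a discrete-time switching first-difference correlated
random walk (DCRWS) to Argos locations. The latent path lives on a
regular grid of step *h* hours (48 h and 6 h are the two resolutions the
package is built around); the grid starts at a track's first fix and has
⌈span/*h*⌉ steps. Each fix is assigned the interval containing it and a
fraction *j* ∈ [0,1) within that interval (a fix exactly on a grid time
starts its interval, *j* = 0). Intervals without fixes are ordinary
missing-data steps: they contribute process terms only. Working directly
in lon/lat degrees follows the original formulation of this model
family; process noise is therefore mildly anisotropic in km at high
latitude, and all distances reported downstream are great-circle
(haversine, R = 6371 km) on the posterior mean path.

Process model, with d_t = x_t − x_{t−1} and state b_t ∈ {1,2}:

    d_t | b_t ~ N( gamma_{b_t} · R(theta_{b_t}) · d_{t−1}, Sigma )

R is the counter-clockwise rotation matrix. The first difference of each
track has no predecessor and gets an independent broad N(0, (1°)²·I)
prior. States follow a Markov chain with alpha_k = P(b_t = 1 | b_{t−1} = k).
State 1 is identified as the persistent (transit) state by enforcing
gamma_1 > gamma_2 in every draw; this also pins the labels across chains.

Observation model: a fix with interval fraction j is predicted by
(1−j)·x_t + j·x_{t+1}; lon and lat residuals are independent scaled
Student-t draws with class-specific (nu, tau). The per-class table is
fixed, not estimated (the usual practice for this model family); the
shipped defaults scale from ≈0.002° (≈250 m, class 3) to ≈0.1°
(≈11 km, class B) with small degrees of freedom for the low classes, and
every entry can be overridden from config. With several animals the
movement parameters (gamma, theta, alpha, Sigma) are shared across
tracks — the hierarchical joint fit — while locations and states remain
per-track.

## Priors

* gamma_1 ~ Beta(5,2), gamma_2 ~ Beta(2,5), truncated to gamma_1 > gamma_2.
* alpha_1 ~ Beta(8,2), alpha_2 ~ Beta(2,8) (states are a priori sticky,
  mean dwell of a few steps).
* theta_b: flat on (−π, π].
* Sigma: half-t(3, scale 1°) on each standard deviation, flat on the
  correlation in (−1, 1).

All hyperparameters are exposed (`PriorSpec`). The defaults are weakly
informative in the direction this model family is normally specified for
marine-mammal telemetry. This is a deliberate design choice: with fully
flat priors, a track that expresses only one behavior leaves the other
state's parameters unidentified, and they drift toward the occupied
state's values until the state labels carry no information — observed
directly during development as posterior modes hovering near 1.3 on
purely transit tracks. The weakly informative defaults keep the
unoccupied state anchored while remaining easily overwhelmed by data
that visit both states.

## Sampler

Metropolis-within-Gibbs, numba-compiled:

* latent locations: single-site bivariate random-walk Metropolis;
* states b_t: single-site Gibbs (exact full conditional from the two
  adjacent transition terms and the local process density);
* alpha: exact conjugate beta updates given the state sequences;
* gamma (logit scale), theta (wrapped), Sigma (log-sds and atanh
  correlation): scalar random-walk Metropolis.

Proposal scales adapt toward fixed acceptance targets during burn-in
only (every 50 iterations), so the post-burn-in chain is a valid fixed
kernel. Location proposal scales and Sigma starting values are
initialised from the data (median per-step displacement of the
interpolated track); chains start over-dispersed with distinct sub-seeds
(chain c uses a deterministic function of seed and c; all sub-seeds stay
below 2³¹). Retention keeps every thin-th post-burn-in draw, so retained
samples = n_chains × (n_iter − n_burnin) / thin exactly; the full-scale
setting (2 chains × 120,000 iterations, 100,000 burn-in, thin 20)
retains 2,000 samples.

Convergence is summarised by the Brooks–Gelman–Rubin potential scale
reduction factor computed per parameter across chains; any R̂ > 1.1
flags the result as non-converged (returned with a warning, never
discarded). arviz serves as an independent cross-check of the diagnostic
in the test suite only.

## Behavioral classification and descriptors

The posterior mean of the sampled states is a continuous mode
m ∈ [1,2]. Classification is conservative and inclusive at the
boundaries: m ≤ 1.25 → transit, m ≥ 1.75 → ARS, otherwise unclassified.
Movement descriptors are computed on the posterior mean path: total
distance (summed haversine), per-state step speeds (displacement over
step duration; a step takes the label of its destination grid time,
whose state governed that displacement), sample SDs (n−1) and min–max
ranges, and km/day using the inclusive day count — both endpoint
calendar dates count, the convention that reproduces the published
deployment table (10 of its 11 rows; one printed duration is internally
inconsistent with its own printed dates by one day).

## Dive analysis

Archival depth bouts are continuous 75 s series of 1–4 h. A true dive is
a maximal run of samples strictly deeper than 10 m (≈ half a body
length), discarding surface respiration. Each sample covers one
resolution interval, so the minimum dive duration is 75 s; the post-dive
interval is the surface time to the next dive within the same bout
(undefined for a bout's last dive), and time is conserved exactly:
durations + post-dive intervals + leading/trailing surface time equal
the bout duration. Bouts with irregular spacing are split at the gaps.
Dives are tagged day/night by geometric solar elevation (no
twilight/refraction allowance) at the dive's start time and the track
position interpolated there, then grouped per grid bin and diel class
(mean, population SD — a single-dive bin reports SD 0 — and range for
depth, duration, post-dive interval). A per-whale pooled day/night
summary is also emitted. Solar geometry is a low-precision NOAA-style
ephemeris implemented in-package (sub-0.1° accuracy, far tighter than
the day/night decision needs).

## Synthetic data

The generator forward-runs exactly the model the fitter assumes, so
every estimand has known truth. Defaults emulate an austral-autumn
deployment off Chilean Northern Patagonia: start (−74°E, −43°N) on
2015-04-15, 200 six-hour steps (50 days), gamma = (0.85, 0.15),
theta = (0, 1.5), alpha = (0.9, 0.1) (mean dwell 10 steps per state),
process-noise sds (0.08°, 0.06°). Observations: Poisson(8) fixes per
transmitting UTC day at uniform times (the "alternate" duty cycle
transmits every other day, reproducing programmed gap structure), Argos
classes drawn from a moderate-quality mix (3/2/1/0/A/B =
10/15/30/20/15/10%), t-distributed errors per class truncated at 5°
(real Argos plausibility screening never delivers fixes thousands of km
out, and the near-Cauchy low classes otherwise would). Two anchor fixes
of class 3 pin the first and last grid times so observed and latent
spans coincide. Dive bouts are Poisson-placed (4/day), 1–4 h long, with
exponential surface spells and flat-bottomed dives whose depth and
duration draw from day or night lognormal/exponential distributions
(day median 60 m vs night 20 m; day mean 300 s vs night 150 s) by solar
elevation at the bout's interpolated position; generated dive depths are
floored at 12 m so the generator's own dive list is the exact extraction
truth.

What the generator does not emulate: real Argos error is not exactly
class-wise-independent t noise, whale movement is not exactly a
first-difference CRW (no bathymetry, currents, or covariate-driven
switching), and dive profiles are flat-bottomed caricatures. Passing
recovery tests therefore demonstrate that the estimator is consistent
with its own generative assumptions at realistic noise and sampling
density — not that those assumptions hold for any particular ocean.

## Problem sizes and verification

The package's standing verification runs at desk scale, chosen so the
full suite completes in minutes on one CPU: recovery uses 20 seeded
replicates of a 200-step track fitted with 2 chains × 15,000 iterations
(5,000 burn-in, thin 10 → 2,000 retained samples), which reproduces the
generating gamma and alpha inside the 95% credible intervals in ≥ 90% of
replicates and classifies ≥ 85% of thresholded steps correctly. The
cross-resolution check (48 h vs 6 h fits of one track) uses
migratory-scale persistence (gamma_1 = 0.97 per 6 h step, dwell ≈ 100
steps), because heading memory shorter than the coarse step genuinely
decorrelates the aggregated process and leaves the coarse model
agnostic — an instructive limitation in its own right. Full-scale chain
settings (120,000 iterations) are supported unchanged; they are simply
longer.

## Known limitations

* Exactly two behavioral states; no covariates on switching; no
  continuous-time formulation.
* Per-class observation parameters are fixed, not estimated.
* The lon/lat process noise is isotropic in degrees, not km.
* Runs of more than a configurable number of empty steps are better
  split than bridged; the pipeline's gap splitting (28 days) handles the
  extreme cases upstream.
* Movement descriptors are computed on the posterior mean path, which
  smooths within data gaps and therefore lower-bounds path length there.
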