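# dcrws — switching correlated random walks for Argos whale telemetry

`dcrws` analyses satellite (Argos) tracks of migrating whales with a
hierarchical Bayesian **two-state switching first-difference correlated
random walk** state-space model, and summarises the archival (time-depth)
records that accompany such deployments. It is aimed at movement
ecologists working with error-prone, irregularly timed Argos fixes who
want regular-step latent tracks, behavioral-state classification
(transit vs area-restricted search), movement descriptors and dive
statistics — plus a fully seeded synthetic-data generator so every stage
of the pipeline can be validated against known ground truth.

## The model

Locations are modelled in lon/lat degrees on a regular time grid (48 h
for broad migratory structure; 6 h for fine-scale behavior). With
first differences *d*ₜ = *x*ₜ − *x*ₜ₋₁ and discrete behavioral state
*b*ₜ ∈ {1 = transit, 2 = ARS}:

- **Process:** *d*ₜ | *b*ₜ ~ N( γ_{bₜ} **R**(θ_{bₜ}) *d*ₜ₋₁, Σ ), where
  γ_b ∈ [0,1] is move persistence, θ_b the mean turn angle, **R** the
  rotation matrix and Σ the process-noise covariance. Transit is the
  persistent state (γ₁ > γ₂ is enforced at every MCMC draw).
- **Switching:** *b*ₜ follows a Markov chain with
  α_k = P(*b*ₜ = 1 | *b*ₜ₋₁ = k).
- **Observation:** a fix at fraction *j* of grid interval *t* is a
  Student-t perturbation of (1−*j*)·*x*ₜ + *j*·*x*ₜ₊₁, with (ν, τ) fixed
  per Argos quality class (3/2/1/0/A/B) — heavy tails for the poor
  classes, so wild fixes are discounted rather than deleted.

Multiple animals are fitted **jointly**: movement parameters are shared
across tracks while locations and states stay individual, which
stabilises state estimation on noisy tracks. Estimation is
Metropolis-within-Gibbs (conjugate beta updates for α, single-site Gibbs
for states, adaptive random-walk Metropolis for locations and the
remaining parameters), with numba-compiled inner loops, Brooks–Gelman–
Rubin R̂ diagnostics, and a label-switching guard. The posterior mean of
the sampled states is a continuous behavioral mode m ∈ [1,2], classified
conservatively: m ≤ 1.25 → transit, m ≥ 1.75 → ARS, otherwise
unclassified.

Around the model sit the supporting stages: Argos ingestion with an
iterative neighbour-speed filter (default 30 km/h) and gap splitting
(default 28 days, "2a"/"2b" style), movement descriptors (great-circle
distances, per-state step speeds, km/day with inclusive day counts),
dive extraction from 75 s depth bouts (true dives exceed 10 m), day/night
tagging by solar elevation, and binning of dive statistics onto the model
grid.

## Worked example

```python
from dcrws import SimScenario, simulate_track, fit_dcrws, MCMCConfig
from dcrws.behavior import descriptors_table

sc = SimScenario(seed=1)                 # 200 six-hour steps, known truth
latent, track = simulate_track(sc)       # 421 noisy duty-cycled fixes
res = fit_dcrws(track, step_hours=6.0,
                mcmc=MCMCConfig(n_chains=2, n_iter=15_000,
                                n_burnin=5_000, thin=10, seed=1))
for k in ("gamma1", "gamma2", "alpha1", "alpha2"):
    s = res.param_summary[k]
    print(f"{k}: {s['mean']:.2f} [{s['ci_lo']:.2f}, {s['ci_hi']:.2f}]")
print(descriptors_table(res.tracks).to_string(index=False))
```

prints

```
gamma1: 0.88 [0.80, 0.95]
gamma2: 0.22 [0.05, 0.41]
alpha1: 0.89 [0.81, 0.95]
alpha2: 0.22 [0.09, 0.40]
track_id  duration_days  distance_km  km_per_day               ARS_speed           transit_speed
     sim             51       2337.3        45.8 1.30 ± 0.60 (0.20–2.26) 2.75 ± 1.23 (0.46–5.87)
```

The generating truth was γ = (0.85, 0.15) and α = (0.9, 0.1); every 95%
credible interval above covers it. The descriptor row reads as: a 51-day
track covering 2337 km (46 km/day), with slow tortuous movement in ARS
steps (1.3 km/h on average) and faster, directed movement in transit
(2.8 km/h).

The same analysis is scriptable from the shell:

```sh
dcrws simulate --seed 1 --out sim/
dcrws prepare  --input sim/argos_fixes.csv --max-speed 30 --gap-days 28 --out prep/
dcrws fit      --tracks prep/cleaned_tracks.csv --step-hours 6 --seed 1 --out fit/
dcrws summarize --posterior fit/posterior_tracks.csv --out descriptors.csv
dcrws dives    --depth sim/depth_series.csv --track fit/posterior_tracks.csv --out dives/
dcrws run-all  --config config.yaml        # everything from one YAML
```

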