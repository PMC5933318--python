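"""Hierarchical Bayesian two-state switching first-difference CRW (DCRWS).

The model regularizes an error-prone, irregularly observed Argos track
onto a fixed time grid (48 h for broad migratory structure, 6 h for
fine-scale behavior) and estimates, by MCMC:

* per-track latent locations ``x_t`` at the grid times,
* per-track discrete behavioral states ``b_t`` in {1 = transit, 2 = ARS},
* movement parameters shared across all tracks (hierarchical joint fit):
  persistence ``gamma_b``, mean turn angle ``theta_b``, process-noise
  covariance ``Sigma`` and Markov switching probabilities ``alpha_k``.

Process model (first differences ``d_t = x_t - x_{t-1}``, lon/lat degrees):

    d_t | b_t ~ N( gamma_{b_t} R(theta_{b_t}) d_{t-1}, Sigma )

with ``R`` the counter-clockwise rotation matrix.  Observation model:
each fix with interval fraction ``j`` is a Student-t perturbation of the
linear interpolation ``(1-j) x_t + j x_{t+1}``, with class-specific
(nu, tau) fixed per Argos quality class.  States switch as a two-state
Markov chain with ``alpha_k = P(b_t = 1 | b_{t-1} = k)``.

Identifiability: state 1 is constrained to be the more persistent state
(``gamma_1 > gamma_2``) at every draw, which pins the transit/ARS
labelling regardless of chain initialization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np

from .argos_io import ArgosFix, Track
from .tdist import TDistParams

logger = logging.getLogger(__name__)

MODEL1_STEP_H = 48.0
MODEL2_STEP_H = 6.0

PARAM_NAMES = ("gamma1", "gamma2", "theta1", "theta2",
               "alpha1", "alpha2", "sigma_lon", "sigma_lat", "rho")

RHAT_THRESHOLD = 1.1


class GridError(ValueError):
    """Track too short (or otherwise unsuitable) for the requested grid."""


@dataclass(frozen=True)
class ProcessParams:
    """Movement parameters shared across individuals.

    gamma: persistence per state, in [0,1], gamma[0] > gamma[1]
    theta: mean turn angle per state, radians in (-pi, pi]
    alpha: alpha[k-1] = P(b_t = 1 | b_{t-1} = k)
    Sigma: 2x2 process-noise covariance, degrees^2
    """

    gamma: tuple[float, float]
    theta: tuple[float, float]
    alpha: tuple[float, float]
    Sigma: np.ndarray

    def __post_init__(self):
        g, a = self.gamma, self.alpha
        if not (0 <= g[0] <= 1 and 0 <= g[1] <= 1):
            raise ValueError("gamma components must lie in [0,1]")
        if not g[0] > g[1]:
            raise ValueError("need gamma_1 > gamma_2 (state 1 = transit "
                             "is the persistent state)")
        if not (0 <= a[0] <= 1 and 0 <= a[1] <= 1):
            raise ValueError("alpha components must lie in [0,1]")
        S = np.asarray(self.Sigma, dtype=float)
        if S.shape != (2, 2) or not np.allclose(S, S.T):
            raise ValueError("Sigma must be symmetric 2x2")
        if np.linalg.eigvalsh(S)[0] <= 0:
            raise ValueError("Sigma must be positive definite")
        object.__setattr__(self, "Sigma", S)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the movement-parameter priors.

    Defaults are weakly informative in the way switching-CRW fits to
    marine-mammal telemetry are usually specified: transit is a priori
    persistent (gamma_1 ~ Beta(5,2)), ARS is not (gamma_2 ~ Beta(2,5)),
    and both states are a priori sticky (alpha_1 ~ Beta(8,2), alpha_2 ~
    Beta(2,8), i.e. mean dwell times of a few steps).  Flat Beta(1,1)
    everywhere is a valid choice but leaves the unoccupied state's
    parameters free to drift toward the occupied state's on tracks that
    express a single behavior, washing out the state labels.  Turn
    angles keep a flat prior on (-pi, pi]; process-noise sds get a
    half-t(3) prior with scale ``sigma_scale`` degrees, correlation a
    flat prior on (-1, 1).
    """

    gamma1: tuple[float, float] = (5.0, 2.0)
    gamma2: tuple[float, float] = (2.0, 5.0)
    alpha1: tuple[float, float] = (8.0, 2.0)
    alpha2: tuple[float, float] = (2.0, 8.0)
    sigma_scale: float = 1.0

    def __post_init__(self):
        for name in ("gamma1", "gamma2", "alpha1", "alpha2"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} beta hyperparameters must be > 0")
        if self.sigma_scale <= 0:
            raise ValueError("sigma_scale must be > 0")

    def gamma_array(self) -> np.ndarray:
        return np.array([*self.gamma1, *self.gamma2], dtype=float)

    def alpha_array(self) -> np.ndarray:
        return np.array([*self.alpha1, *self.alpha2], dtype=float)


@dataclass(frozen=True)
class MCMCConfig:
    """Chain bookkeeping: samples retained = n_chains*(n_iter-n_burnin)//thin."""

    n_chains: int = 2
    n_iter: int = 120_000
    n_burnin: int = 100_000
    thin: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.retained_per_chain < 100:
            raise ValueError("need >= 100 retained samples per chain")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin

    @property
    def retained_samples(self) -> int:
        return self.n_chains * self.retained_per_chain


@dataclass(frozen=True)
class RegularGrid:
    """Regular time grid with each fix's (interval, fraction) assignment.

    times[k] = t0 + k*step for k = 0..n_steps; a fix at fraction j of
    interval t predicts the observation (1-j)*x_t + j*x_{t+1}.  Intervals
    without any fix are ordinary missing-data steps.
    """

    t0: datetime
    step_hours: float
    n_steps: int
    fix_interval: np.ndarray  # (n_fixes,) int
    fix_j: np.ndarray         # (n_fixes,) float in [0,1)

    @property
    def n_times(self) -> int:
        return self.n_steps + 1

    @property
    def times(self) -> list[datetime]:
        return [self.t0 + timedelta(hours=self.step_hours * k)
                for k in range(self.n_steps + 1)]


def build_grid(track: Track, step_hours: float) -> RegularGrid:
    """Lay a regular grid over a track and assign every fix to an interval.

    The grid starts at the first fix; n_steps = ceil(span / step).  A fix
    exactly on a grid time belongs to the interval it starts (j = 0).
    """
    if step_hours <= 0:
        raise ValueError("step_hours must be positive")
    t = track.times()
    span_h = (t[-1] - t[0]) / 3600.0
    if span_h < 2 * step_hours:
        raise GridError(f"track {track.track_id}: span {span_h:.1f} h is "
                        f"shorter than 2 steps of {step_hours} h")
    n_steps = int(math.ceil(span_h / step_hours - 1e-9))
    rel = (t - t[0]) / 3600.0 / step_hours
    interval = np.floor(rel + 1e-9).astype(np.int64)
    j = np.clip(rel - interval, 0.0, None)
    return RegularGrid(t0=track.fixes[0].time, step_hours=float(step_hours),
                       n_steps=n_steps, fix_interval=interval, fix_j=j)


def rotation_matrix(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def process_model_step(x_prev2, x_prev, b: int, params: ProcessParams,
                       noise_draw=(0.0, 0.0)) -> np.ndarray:
    """One deterministic-plus-noise step of the first-difference CRW.

    x_next = x_prev + gamma_b R(theta_b) (x_prev - x_prev2) + noise.
    """
    if b not in (1, 2):
        raise ValueError("behavioral state must be 1 or 2")
    x_prev2 = np.asarray(x_prev2, dtype=float)
    x_prev = np.asarray(x_prev, dtype=float)
    g = params.gamma[b - 1]
    R = rotation_matrix(params.theta[b - 1])
    return x_prev + g * (R @ (x_prev - x_prev2)) + np.asarray(noise_draw, float)


def switch_states(b_prev: int, params: ProcessParams, uniform_draw: float) -> int:
    """Markov switch: next state is 1 with probability alpha_{b_prev}."""
    if b_prev not in (1, 2):
        raise ValueError("behavioral state must be 1 or 2")
    return 1 if uniform_draw < params.alpha[b_prev - 1] else 2


def observation_loglik(fix: ArgosFix, x_start, x_end, j: float,
                       tparams: TDistParams) -> float:
    """Log-likelihood of one fix given its interval's two grid locations.

    Predicted location is (1-j)*x_start + j*x_end; lon and lat residuals
    are independent scaled Student-t draws with class-specific (nu, tau).
    """
    if not 0.0 <= j < 1.0:
        raise ValueError("interval fraction j must lie in [0,1)")
    from ._sampler import t_logpdf
    nu = tparams.nu(fix.loc_class)
    tau = tparams.tau(fix.loc_class)
    x_start = np.asarray(x_start, float)
    x_end = np.asarray(x_end, float)
    pred = (1.0 - j) * x_start + j * x_end
    return (t_logpdf(fix.lon - pred[0], nu[0], tau[0])
            + t_logpdf(fix.lat - pred[1], nu[1], tau[1]))


def gelman_rubin(chains) -> float:
    """Brooks–Gelman–Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_samples).  R-hat compares the pooled
    variance estimate ((n-1)/n W + B/n) to the within-chain variance W;
    values near 1 indicate the chains have mixed.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = c.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful diagnostic")
    means = c.mean(axis=1)
    W = c.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(math.sqrt(var_hat / W))


@dataclass(frozen=True)
class LatentPath:
    """True regular-step locations and behavioral states (known only in
    simulation; the estimand of the fit)."""

    t0: datetime
    step_hours: float
    x: np.ndarray  # (n_times, 2) lon/lat degrees
    b: np.ndarray  # (n_times,) states in {1,2}

    def __post_init__(self):
        if self.x.shape[0] != self.b.shape[0]:
            raise ValueError("x and b must have equal length")
        if not np.isin(self.b, (1, 2)).all():
            raise ValueError("states must be 1 or 2")

    @property
    def n_times(self) -> int:
        return self.x.shape[0]

    @property
    def times(self) -> list[datetime]:
        return [self.t0 + timedelta(hours=self.step_hours * k)
                for k in range(self.n_times)]

    def position_at(self, t: datetime) -> tuple[float, float]:
        """Linear interpolation of the true path at an arbitrary time."""
        rel = (t - self.t0).total_seconds() / 3600.0 / self.step_hours
        rel = min(max(rel, 0.0), self.n_times - 1.0)
        k = min(int(rel), self.n_times - 2)
        j = rel - k
        p = (1 - j) * self.x[k] + j * self.x[k + 1]
        return float(p[0]), float(p[1])


@dataclass
class TrackPosterior:
    """Per-track posterior summary on the regular grid."""

    track_id: str
    grid: RegularGrid
    mean_lon: np.ndarray
    mean_lat: np.ndarray
    ci_lon: np.ndarray   # (n_times, 2) 2.5/97.5 percentiles
    ci_lat: np.ndarray
    mode: np.ndarray     # mean behavioral mode m in [1,2] per grid time


@dataclass
class FitResult:
    """Joint hierarchical fit: shared parameters + per-track posteriors."""

    tracks: list[TrackPosterior]
    param_samples: dict[str, np.ndarray]       # name -> (n_chains, K)
    param_summary: dict[str, dict[str, float]]  # mean / ci / rhat per name
    rhat: dict[str, float]
    converged: bool
    acceptance: dict[str, float]
    config: MCMCConfig

    @property
    def retained_samples(self) -> int:
        return sum(v.size for v in self.param_samples.values()) \
            // len(self.param_samples)

    def params_mean(self) -> ProcessParams:
        s = self.param_summary
        return ProcessParams(
            gamma=(s["gamma1"]["mean"], s["gamma2"]["mean"]),
            theta=(s["theta1"]["mean"], s["theta2"]["mean"]),
            alpha=(s["alpha1"]["mean"], s["alpha2"]["mean"]),
            Sigma=_sigma_from(s["sigma_lon"]["mean"], s["sigma_lat"]["mean"],
                              s["rho"]["mean"]),
        )


def _sigma_from(s1: float, s2: float, rho: float) -> np.ndarray:
    return np.array([[s1 * s1, rho * s1 * s2], [rho * s1 * s2, s2 * s2]])


def _interp_init(track: Track, grid: RegularGrid, rng: np.random.Generator,
                 jitter: float) -> np.ndarray:
    """Linear-in-time interpolation of the fixes at grid times, jittered."""
    t = track.times()
    xy = track.lonlat()
    gt = t[0] + np.arange(grid.n_times) * grid.step_hours * 3600.0
    lon = np.interp(gt, t, xy[:, 0])
    lat = np.interp(gt, t, xy[:, 1])
    out = np.column_stack([lon, lat])
    return out + jitter * rng.standard_normal(out.shape)


def _pack_tracks(tracks: Sequence[Track], grids: Sequence[RegularGrid],
                 tdist: TDistParams):
    """Concatenate all tracks into the flat site/observation arrays."""
    offsets = np.zeros(len(tracks) + 1, dtype=np.int64)
    for i, g in enumerate(grids):
        offsets[i + 1] = offsets[i] + g.n_times
    N = int(offsets[-1])
    tr_of = np.empty(N, dtype=np.int64)
    loc_of = np.empty(N, dtype=np.int64)
    for i in range(len(tracks)):
        tr_of[offsets[i]:offsets[i + 1]] = i
        loc_of[offsets[i]:offsets[i + 1]] = np.arange(grids[i].n_times)

    ys, aa, bb, jj, nus, taus = [], [], [], [], [], []
    for i, (tr, g) in enumerate(zip(tracks, grids)):
        nu, tau = tdist.arrays(tr.loc_classes())
        xy = tr.lonlat()
        for r in range(len(tr)):
            a = int(offsets[i] + g.fix_interval[r])
            j = float(g.fix_j[r])
            bsite = min(a + 1, int(offsets[i + 1] - 1))
            ys.append(xy[r])
            aa.append(a)
            bb.append(bsite)
            jj.append(j if bsite > a else 0.0)
            nus.append(nu[r])
            taus.append(tau[r])
    obs_y = np.asarray(ys, float).reshape(-1, 2)
    obs_a = np.asarray(aa, np.int64)
    obs_bsite = np.asarray(bb, np.int64)
    obs_j = np.asarray(jj, float)
    obs_nu = np.asarray(nus, float).reshape(-1, 2)
    obs_tau = np.asarray(taus, float).reshape(-1, 2)

    touch: list[list[int]] = [[] for _ in range(N)]
    for m in range(obs_a.size):
        touch[obs_a[m]].append(m)
        if obs_j[m] > 0.0 and obs_bsite[m] != obs_a[m]:
            touch[obs_bsite[m]].append(m)
    sop = np.zeros(N + 1, dtype=np.int64)
    for g_ in range(N):
        sop[g_ + 1] = sop[g_] + len(touch[g_])
    soi = np.fromiter((m for lst in touch for m in lst), dtype=np.int64,
                      count=int(sop[-1]))
    return offsets, tr_of, loc_of, (obs_y, obs_a, obs_bsite, obs_j,
                                    obs_nu, obs_tau, sop, soi)


def fit_dcrws(tracks: Sequence[Track] | Track,
              step_hours: float = MODEL1_STEP_H,
              mcmc: MCMCConfig | None = None,
              tdist: TDistParams | None = None,
              priors: PriorSpec | None = None,
              first_diff_sd: float = 1.0) -> FitResult:
    """Jointly fit the switching CRW to one or more tracks by MCMC.

    All tracks share ProcessParams (hierarchical joint estimation); latent
    locations and states are per track.  Chains start from over-dispersed
    initial values drawn with distinct sub-seeds; proposal scales adapt
    during burn-in only.  Any parameter with R-hat > 1.1 flags the result
    as non-converged (returned with a warning, never discarded).
    """
    from ._sampler import run_chain

    if isinstance(tracks, Track):
        tracks = [tracks]
    if not tracks:
        raise ValueError("need at least one track")
    mcmc = mcmc or MCMCConfig()
    tdist = tdist or TDistParams()
    priors = priors or PriorSpec()
    grids = [build_grid(tr, step_hours) for tr in tracks]
    offsets, tr_of, loc_of, obs = _pack_tracks(tracks, grids, tdist)
    N = int(offsets[-1])
    K = mcmc.retained_per_chain

    # data scale of one grid step, from the interpolated paths: drives the
    # initial location-proposal scale and the sigma starting values
    rng0 = np.random.default_rng(int(mcmc.seed) % (2**31 - 1))
    diffs = np.vstack([np.diff(_interp_init(tr, g, rng0, jitter=0.0), axis=0)
                       for tr, g in zip(tracks, grids)])
    step_scale = float(np.median(np.abs(diffs))) if diffs.size else 0.05
    step_scale = max(step_scale, 1e-3)

    param_chains = np.empty((mcmc.n_chains, K, 9))
    x_chains = np.empty((mcmc.n_chains, K, N, 2))
    b_mean = np.zeros(N)
    acc = np.zeros(2)
    for c in range(mcmc.n_chains):
        sub_seed = int((mcmc.seed * 1_000_003 + 7919 * (c + 1)) % (2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        x0 = np.vstack([_interp_init(tr, g, rng,
                                     jitter=0.5 * step_scale * (c + 1))
                        for tr, g in zip(tracks, grids)])
        b0 = rng.integers(1, 3, size=N).astype(np.int64)
        g1 = rng.uniform(0.6, 0.95)
        g2 = rng.uniform(0.05, 0.4)
        params0 = np.array([
            g1, g2,
            rng.uniform(-0.5, 0.5), rng.uniform(-0.5, 0.5),
            rng.uniform(0.7, 0.95), rng.uniform(0.05, 0.3),
            step_scale * rng.uniform(0.5, 2.0),
            step_scale * rng.uniform(0.5, 2.0), 0.0,
        ])
        pk, xk, bs, a = run_chain(
            sub_seed, mcmc.n_iter, mcmc.n_burnin, mcmc.thin,
            x0.astype(float), b0, tr_of, loc_of, *obs,
            params0, float(first_diff_sd), float(priors.sigma_scale),
            priors.gamma_array(), priors.alpha_array(),
            0.5 * step_scale, len(tracks))
        param_chains[c] = pk
        x_chains[c] = xk
        b_mean += bs
        acc += a
    b_mean /= mcmc.retained_samples
    acc /= mcmc.n_chains

    rhat = {name: gelman_rubin(param_chains[:, :, k])
            for k, name in enumerate(PARAM_NAMES)}
    converged = all(v <= RHAT_THRESHOLD for v in rhat.values())
    if not converged:
        bad = {k: round(v, 3) for k, v in rhat.items() if v > RHAT_THRESHOLD}
        logger.warning("chains not converged (R-hat > %.1f): %s",
                       RHAT_THRESHOLD, bad)

    param_samples = {name: param_chains[:, :, k]
                     for k, name in enumerate(PARAM_NAMES)}
    summary = {}
    for name, s in param_samples.items():
        flat = s.ravel()
        lo, hi = np.percentile(flat, [2.5, 97.5])
        summary[name] = {"mean": float(flat.mean()), "ci_lo": float(lo),
                         "ci_hi": float(hi), "rhat": rhat[name]}

    flat_x = x_chains.reshape(-1, N, 2)
    mean_xy = flat_x.mean(axis=0)
    lo_xy = np.percentile(flat_x, 2.5, axis=0)
    hi_xy = np.percentile(flat_x, 97.5, axis=0)
    out_tracks = []
    for i, (tr, g) in enumerate(zip(tracks, grids)):
        sl = slice(int(offsets[i]), int(offsets[i + 1]))
        mode = b_mean[sl].copy()
        if mode.size > 1:
            mode[0] = mode[1]  # site 0 has no governing step; inherit
        out_tracks.append(TrackPosterior(
            track_id=tr.track_id, grid=g,
            mean_lon=mean_xy[sl, 0], mean_lat=mean_xy[sl, 1],
            ci_lon=np.column_stack([lo_xy[sl, 0], hi_xy[sl, 0]]),
            ci_lat=np.column_stack([lo_xy[sl, 1], hi_xy[sl, 1]]),
            mode=mode))
    return FitResult(tracks=out_tracks, param_samples=param_samples,
                     param_summary=summary, rhat=rhat, converged=converged,
                     acceptance={"locations": float(acc[0]),
                                 "parameters": float(acc[1])},
                     config=mcmc)
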