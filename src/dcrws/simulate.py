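"""Synthetic data with known ground truth for every estimand.

Forward-simulates the exact generative model the fitter assumes: a
two-state switching first-difference CRW in lon/lat degrees, observed
through duty-cycled Argos fixes with class-dependent Student-t error,
plus diel-structured archival dive bouts along the latent path.  Every
simulation is driven by one seed and is bit-reproducible.

Defaults emulate an austral-autumn blue whale deployment off Chilean
Northern Patagonia: 6 h latent steps, daily transmission (the tags'
pre-June schedule; "alternate" reproduces the every-other-day duty
cycle), a realistic Argos quality mix dominated by classes A/B, and
dives that are deeper and longer by day than by night.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone

import numpy as np

from .argos_io import ArgosFix, Track
from .dive import SAMPLE_SECONDS, Dive, DiveBout
from .geo import is_daylight
from .ssm import LatentPath, ProcessParams
from .tdist import TDistParams

#: moderate-quality Argos class mix; heavier-tailed mixes (A/B-dominated
#: deployments) are expressed through the scenario's loc_class_mix
DEFAULT_CLASS_MIX = {"3": 0.10, "2": 0.15, "1": 0.30,
                     "0": 0.20, "A": 0.15, "B": 0.10}

#: truncation of t-distributed location error (degrees); the near-Cauchy
#: low classes otherwise produce fixes thousands of km out, which real
#: Argos plausibility screening never delivers
ERROR_TRUNC_DEG = 5.0


def default_process_params() -> ProcessParams:
    """Well-separated transit/ARS dynamics with ~10-step mean dwell times."""
    return ProcessParams(gamma=(0.85, 0.15), theta=(0.0, 1.5),
                         alpha=(0.9, 0.1),
                         Sigma=np.diag([0.08**2, 0.06**2]))


@dataclass(frozen=True)
class DiveRegime:
    """Day/night dive-generating distributions (lognormal depths, m)."""

    day_depth_median: float = 60.0
    night_depth_median: float = 20.0
    depth_log_sd: float = 0.5
    day_duration_mean_s: float = 300.0
    night_duration_mean_s: float = 150.0
    surface_mean_s: float = 150.0
    min_depth: float = 12.0          # keep every generated dive a true dive
    bouts_per_day: float = 4.0


@dataclass(frozen=True)
class SimScenario:
    """Everything needed to forward-simulate one tagged whale."""

    params: ProcessParams = field(default_factory=default_process_params)
    tdist: TDistParams = field(default_factory=TDistParams)
    n_steps: int = 200
    step_hours: float = 6.0
    t0: datetime = datetime(2015, 4, 15, tzinfo=timezone.utc)
    lon0: float = -74.0
    lat0: float = -43.0
    duty_cycle: str = "daily"        # "daily" | "alternate"
    fixes_per_day: float = 8.0
    loc_class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    dive_regime: DiveRegime = field(default_factory=DiveRegime)
    start_state: int | None = None   # None -> draw from stationary law
    tag_id: str = "sim"
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.loc_class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("loc_class_mix probabilities must sum to 1")
        if self.fixes_per_day <= 0 or self.n_steps < 2:
            raise ValueError("need positive fix rate and >= 2 steps")
        if self.duty_cycle not in ("daily", "alternate"):
            raise ValueError("duty_cycle must be 'daily' or 'alternate'")

    def with_seed(self, seed: int) -> "SimScenario":
        return replace(self, seed=seed)


def stationary_state1_prob(params: ProcessParams) -> float:
    """P(state 1) under the stationary law of the two-state switch chain."""
    a1, a2 = params.alpha
    denom = 1.0 - a1 + a2
    return 0.5 if denom == 0 else a2 / denom


def simulate_latent(scenario: SimScenario,
                    rng: np.random.Generator | None = None) -> LatentPath:
    """Forward-run the switching CRW process model."""
    rng = rng or np.random.default_rng(scenario.seed)
    p = scenario.params
    n = scenario.n_steps
    L = np.linalg.cholesky(p.Sigma)
    x = np.empty((n + 1, 2))
    b = np.empty(n + 1, dtype=np.int64)
    x[0] = (scenario.lon0, scenario.lat0)
    if scenario.start_state is None:
        b[1] = 1 if rng.random() < stationary_state1_prob(p) else 2
    else:
        b[1] = scenario.start_state
    d = L @ rng.standard_normal(2)
    x[1] = x[0] + d
    b[0] = b[1]
    for t in range(2, n + 1):
        a_prev = p.alpha[b[t - 1] - 1]
        b[t] = 1 if rng.random() < a_prev else 2
        g = p.gamma[b[t] - 1]
        th = p.theta[b[t] - 1]
        c, s = math.cos(th), math.sin(th)
        d = (g * np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
             + L @ rng.standard_normal(2))
        x[t] = x[t - 1] + d
    return LatentPath(t0=scenario.t0, step_hours=scenario.step_hours, x=x, b=b)


def _transmitting(day_index: int, duty_cycle: str) -> bool:
    return duty_cycle == "daily" or day_index % 2 == 0


def simulate_track(scenario: SimScenario) -> tuple[LatentPath, Track]:
    """Simulate the latent path and its duty-cycled, noisy Argos track.

    Fix counts per transmitting UTC day are Poisson(fixes_per_day) with
    uniform times within the day; each fix interpolates the latent path
    at its fraction j and adds per-class t-distributed error (truncated
    at ERROR_TRUNC_DEG degrees).  First/last latent times always receive
    one good-quality fix so the observed span matches the latent span.
    """
    rng = np.random.default_rng(scenario.seed)
    latent = simulate_latent(scenario, rng)
    span_s = scenario.n_steps * scenario.step_hours * 3600.0
    n_days = int(math.ceil(span_s / 86400.0))

    classes = list(scenario.loc_class_mix)
    probs = np.array([scenario.loc_class_mix[c] for c in classes])

    fix_times: list[float] = [0.0, span_s]
    fix_classes: list[str] = ["3", "3"]  # anchor fixes, best quality
    for day in range(n_days):
        if not _transmitting(day, scenario.duty_cycle):
            continue
        k = rng.poisson(scenario.fixes_per_day)
        offs = np.sort(rng.uniform(0.0, 86400.0, size=k)) + day * 86400.0
        for off in offs:
            if 0.0 < off < span_s:
                fix_times.append(float(off))
                fix_classes.append(classes[rng.choice(len(classes), p=probs)])
    order = np.argsort(fix_times)

    fixes = []
    for idx in order:
        off, cls = fix_times[idx], fix_classes[idx]
        t = scenario.t0 + timedelta(seconds=off)
        lon, lat = latent.position_at(t)
        nu, tau = scenario.tdist.nu(cls), scenario.tdist.tau(cls)
        err = np.clip([tau[0] * rng.standard_t(nu[0]),
                       tau[1] * rng.standard_t(nu[1])],
                      -ERROR_TRUNC_DEG, ERROR_TRUNC_DEG)
        fixes.append(ArgosFix(tag_id=scenario.tag_id, time=t,
                              lon=lon + err[0],
                              lat=float(np.clip(lat + err[1], -90.0, 90.0)),
                              loc_class=cls))
    return latent, Track(track_id=scenario.tag_id, fixes=fixes)


def simulate_dives(scenario: SimScenario, latent: LatentPath
                   ) -> tuple[list[DiveBout], list[Dive]]:
    """Generate diel-structured dive bouts along a latent path.

    Bouts of 1–4 h at the archival resolution start at Poisson-placed
    times; within a bout, surface spells (exponential, U(0,5) m samples)
    alternate with flat-bottomed dives whose depth and duration come from
    the day or the night distribution by solar elevation at the bout's
    interpolated position.  Returns the bouts and the generator's own
    list of true dives (the ground truth for extraction tests).
    """
    rng = np.random.default_rng(scenario.seed + 1)
    reg = scenario.dive_regime
    res = SAMPLE_SECONDS
    span_s = scenario.n_steps * scenario.step_hours * 3600.0
    n_bouts = rng.poisson(reg.bouts_per_day * span_s / 86400.0)
    starts = np.sort(rng.uniform(0.0, max(span_s - 4 * 3600.0, 1.0), n_bouts))

    bouts: list[DiveBout] = []
    truth: list[Dive] = []
    prev_end = -math.inf
    for s0 in starts:
        if s0 < prev_end:  # bouts must not overlap
            continue
        dur_s = rng.uniform(3600.0, 4 * 3600.0)
        n_samp = int(dur_s // res)
        prev_end = s0 + n_samp * res
        start_t = scenario.t0 + timedelta(seconds=float(s0))
        lon, lat = latent.position_at(start_t)
        day = is_daylight(start_t, lon, lat)
        depth_med = reg.day_depth_median if day else reg.night_depth_median
        dur_mean = reg.day_duration_mean_s if day else reg.night_duration_mean_s

        depths = np.empty(n_samp)
        i = 0
        dive_runs: list[tuple[int, int, float]] = []
        while i < n_samp:
            k_surf = 1 + rng.poisson(reg.surface_mean_s / res)
            k_surf = min(k_surf, n_samp - i)
            depths[i:i + k_surf] = rng.uniform(0.0, 5.0, k_surf)
            i += k_surf
            if i >= n_samp:
                break
            depth = max(reg.min_depth,
                        depth_med * math.exp(reg.depth_log_sd
                                             * rng.standard_normal()))
            k_dive = max(1, int(round(rng.exponential(dur_mean) / res)))
            k_dive = min(k_dive, n_samp - i)
            if k_dive > 0:
                depths[i:i + k_dive] = depth
                dive_runs.append((i, i + k_dive, depth))
                i += k_dive
        bout = DiveBout(tag_id=scenario.tag_id, start=start_t, depths=depths,
                        resolution_s=res)
        bouts.append(bout)
        for k, (a, b_, depth) in enumerate(dive_runs):
            nxt = dive_runs[k + 1][0] if k + 1 < len(dive_runs) else None
            truth.append(Dive(
                tag_id=scenario.tag_id,
                start=start_t + timedelta(seconds=res * a),
                end=start_t + timedelta(seconds=res * b_),
                max_depth=depth, duration_s=res * (b_ - a),
                post_dive_interval_s=(res * (nxt - b_)
                                      if nxt is not None else None),
                diel="day" if day else "night"))
    return bouts, truth
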