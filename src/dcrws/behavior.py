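"""Behavioral-state classification and movement descriptors.

The MCMC mean of the sampled discrete states is a continuous behavioral
mode m in [1,2].  Conservative thresholds turn it into labels: m <= 1.25
is transit (persistent, low-turn movement; migratory), m >= 1.75 is
area-restricted search (ARS; high turning, foraging-associated), and
values in between stay unclassified.  Movement descriptors (total
distance, per-state step speeds, distance per day) are computed on the
posterior mean path at the model's regular time step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .argos_io import track_duration
from .geo import haversine_km
from .ssm import TrackPosterior

TRANSIT = "transit"
ARS = "ARS"
UNCLASSIFIED = "unclassified"

TRANSIT_MAX_MODE = 1.25
ARS_MIN_MODE = 1.75


def classify_mode(m: float) -> str:
    """Label a mean behavioral mode; thresholds are inclusive.

    1 <= m <= 1.25 -> transit, 1.75 <= m <= 2 -> ARS, else unclassified.
    """
    if not 1.0 <= m <= 2.0:
        raise ValueError(f"behavioral mode {m} outside [1,2]")
    if m <= TRANSIT_MAX_MODE:
        return TRANSIT
    if m >= ARS_MIN_MODE:
        return ARS
    return UNCLASSIFIED


def classify_modes(modes) -> list[str]:
    return [classify_mode(float(m)) for m in np.asarray(modes, float)]


def step_speed(x_start, x_end, step_hours: float) -> float:
    """Great-circle speed (km/h) between consecutive grid locations."""
    d = float(haversine_km(x_start[0], x_start[1], x_end[0], x_end[1]))
    return d / step_hours


@dataclass
class SpeedSummary:
    mean: float
    sd: float
    min: float
    max: float
    n_steps: int

    def __str__(self) -> str:
        sd = 0.0 if math.isnan(self.sd) else self.sd
        return f"{self.mean:.2f} ± {sd:.2f} ({self.min:.2f}–{self.max:.2f})"


@dataclass
class MovementDescriptors:
    """Per-track movement summary in the style of a deployment table."""

    track_id: str
    duration_days: int
    total_distance_km: float
    km_per_day: float
    speeds: dict[str, SpeedSummary]  # per label; absent labels missing

    def to_row(self) -> dict:
        row = {"track_id": self.track_id,
               "duration_days": self.duration_days,
               "distance_km": round(self.total_distance_km, 1),
               "km_per_day": round(self.km_per_day, 1)}
        for label in (ARS, TRANSIT):
            s = self.speeds.get(label)
            row[f"{label}_speed"] = str(s) if s else "na"
        return row


def _speed_summary(speeds: np.ndarray) -> SpeedSummary:
    sd = float(np.std(speeds, ddof=1)) if speeds.size > 1 else float("nan")
    return SpeedSummary(mean=float(np.mean(speeds)), sd=sd,
                        min=float(np.min(speeds)), max=float(np.max(speeds)),
                        n_steps=int(speeds.size))


def summarize_track(post: TrackPosterior) -> MovementDescriptors:
    """Movement descriptors from a fitted track's posterior mean path.

    Steps take the label of their destination grid time (the state that
    governed that displacement).  Total distance is the haversine length
    of the mean path; km/day divides it by the inclusive track duration.
    SDs are sample SDs over steps; ranges are min–max of step speeds.
    """
    lon, lat = post.mean_lon, post.mean_lat
    if lon.size < 2:
        raise ValueError("need at least 2 grid locations")
    seg_km = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    speeds = seg_km / post.grid.step_hours
    labels = np.array(classify_modes(post.mode[1:]))
    total = float(seg_km.sum())
    times = post.grid.times
    days = track_duration(times[0], times[-1])
    per_state = {}
    for label in (TRANSIT, ARS, UNCLASSIFIED):
        sel = speeds[labels == label]
        if sel.size:
            per_state[label] = _speed_summary(sel)
    return MovementDescriptors(track_id=post.track_id, duration_days=days,
                               total_distance_km=total,
                               km_per_day=total / days, speeds=per_state)


def descriptors_table(posts) -> pd.DataFrame:
    """Stack per-track descriptors into a deployment-summary table."""
    return pd.DataFrame([summarize_track(p).to_row() for p in posts])


def labelled_steps_frame(post: TrackPosterior) -> pd.DataFrame:
    """Per-grid-time CSV payload: mean location, CI, mode and label."""
    labels = classify_modes(post.mode)
    return pd.DataFrame({
        "track_id": post.track_id,
        "time": [t.isoformat() for t in post.grid.times],
        "lon": post.mean_lon, "lat": post.mean_lat,
        "lon_lo": post.ci_lon[:, 0], "lon_hi": post.ci_lon[:, 1],
        "lat_lo": post.ci_lat[:, 0], "lat_hi": post.ci_lat[:, 1],
        "mode": post.mode, "label": labels,
    })
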