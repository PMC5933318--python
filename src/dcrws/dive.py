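"""Dive extraction and diel summaries from archival-tag depth bouts.

MK10-style tags record depth as "time series" bouts: continuous 75 s
sampling for 1–4 h.  A true dive is a maximal run of samples deeper than
a threshold (~10 m, half a body length), which discards surface
breathing.  Three statistics are taken per dive — maximum depth, duration
and post-dive (inter-dive) interval within the bout — then grouped onto
the state-space model's regular grid bins and split day/night by solar
elevation at the dive's start position.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .geo import is_daylight
from .ssm import RegularGrid

SAMPLE_SECONDS = 75.0
DIVE_THRESHOLD_M = 10.0
DAY = "day"
NIGHT = "night"


class BoutSpacingError(ValueError):
    """Depth samples are not on the fixed bout resolution."""


@dataclass(frozen=True)
class DiveBout:
    """One continuous depth recording at fixed resolution."""

    tag_id: str
    start: datetime
    depths: np.ndarray              # metres, >= 0
    resolution_s: float = SAMPLE_SECONDS

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        if d.ndim != 1 or d.size < 2:
            raise ValueError("bout needs a 1-d series of >= 2 depth samples")
        if (d < 0).any():
            raise ValueError("depths must be non-negative")
        object.__setattr__(self, "depths", d)

    @property
    def duration_s(self) -> float:
        return self.depths.size * self.resolution_s

    def sample_times(self) -> list[datetime]:
        return [self.start + timedelta(seconds=self.resolution_s * i)
                for i in range(self.depths.size)]


def bout_from_samples(tag_id: str, times: Sequence[datetime],
                      depths, resolution_s: float = SAMPLE_SECONDS) -> DiveBout:
    """Build a bout from timestamped samples, enforcing regular spacing."""
    dt = np.diff([t.timestamp() for t in times])
    if dt.size and not np.allclose(dt, resolution_s, atol=1.0):
        raise BoutSpacingError(
            f"tag {tag_id}: sample spacing deviates from {resolution_s} s")
    return DiveBout(tag_id=tag_id, start=times[0],
                    depths=np.asarray(depths, float),
                    resolution_s=resolution_s)


@dataclass(frozen=True)
class Dive:
    """One true dive with the three bout-level statistics."""

    tag_id: str
    start: datetime
    end: datetime
    max_depth: float                 # m
    duration_s: float
    post_dive_interval_s: float | None  # to next dive in same bout
    diel: str | None = None


def detect_dives(bout: DiveBout,
                 threshold: float = DIVE_THRESHOLD_M) -> list[Dive]:
    """Extract maximal runs of samples strictly deeper than ``threshold``.

    Each sample covers one resolution interval starting at its timestamp,
    so a single-sample dive lasts exactly one resolution (75 s), and the
    inter-dive interval is the surface time between a run's end and the
    next run's start.  Dives never span bouts.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    deep = bout.depths > threshold
    if not deep.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], deep,
                                                   [False])).astype(int)))
    starts, ends = edges[::2], edges[1::2]  # ends exclusive
    res = bout.resolution_s
    dives = []
    for k, (a, b) in enumerate(zip(starts, ends)):
        start_t = bout.start + timedelta(seconds=res * float(a))
        end_t = bout.start + timedelta(seconds=res * float(b))
        if k + 1 < len(starts):
            pdi = res * float(starts[k + 1] - b)
        else:
            pdi = None
        dives.append(Dive(tag_id=bout.tag_id, start=start_t, end=end_t,
                          max_depth=float(bout.depths[a:b].max()),
                          duration_s=res * float(b - a),
                          post_dive_interval_s=pdi))
    return dives


def diel_tag(time: datetime, lon: float, lat: float) -> str:
    """"day" iff the sun is geometrically above the horizon there and then."""
    return DAY if is_daylight(time, lon, lat) else NIGHT


def tag_dives_diel(dives: Iterable[Dive],
                   position_at: Callable[[datetime], tuple[float, float]]
                   ) -> list[Dive]:
    """Attach day/night to each dive using its start time and the track.

    ``position_at`` interpolates the fitted track (lon, lat) at a time.
    """
    out = []
    for d in dives:
        lon, lat = position_at(d.start)
        out.append(Dive(tag_id=d.tag_id, start=d.start, end=d.end,
                        max_depth=d.max_depth, duration_s=d.duration_s,
                        post_dive_interval_s=d.post_dive_interval_s,
                        diel=diel_tag(d.start, lon, lat)))
    return out


_STATS = ("max_depth", "duration_s", "post_dive_interval_s")


def dives_to_frame(dives: Iterable[Dive]) -> pd.DataFrame:
    return pd.DataFrame([{
        "tag_id": d.tag_id, "start": d.start.isoformat(),
        "end": d.end.isoformat(), "max_depth": d.max_depth,
        "duration_s": d.duration_s,
        "post_dive_interval_s": d.post_dive_interval_s,
        "diel": d.diel,
    } for d in dives])


def bin_dive_stats(dives: Sequence[Dive], grid: RegularGrid) -> pd.DataFrame:
    """Mean ± SD and range of the three dive statistics per (bin, diel).

    A dive joins the grid interval containing its start time; bins with no
    dives are simply absent.  SD is the population SD (a single dive in a
    bin reports SD 0).  Dives lacking a post-dive interval (last of their
    bout) contribute to the other statistics only.
    """
    rows = []
    t0 = grid.t0.timestamp()
    step_s = grid.step_hours * 3600.0
    for d in dives:
        rel = (d.start.timestamp() - t0) / step_s
        if rel < 0 or rel > grid.n_steps:
            continue
        rows.append({"bin": min(int(rel), grid.n_steps - 1),
                     "diel": d.diel,
                     "max_depth": d.max_depth,
                     "duration_s": d.duration_s,
                     "post_dive_interval_s": d.post_dive_interval_s})
    if not rows:
        return pd.DataFrame(columns=["bin", "diel", "n_dives"])
    df = pd.DataFrame(rows)
    out = []
    for (b, diel), grp in df.groupby(["bin", "diel"], dropna=False):
        rec = {"bin": int(b), "diel": diel, "n_dives": len(grp),
               "bin_start": (grid.t0
                             + timedelta(seconds=step_s * int(b))).isoformat()}
        for stat in _STATS:
            vals = grp[stat].dropna().to_numpy(float)
            if vals.size == 0:
                continue
            rec[f"{stat}_mean"] = float(vals.mean())
            rec[f"{stat}_sd"] = float(vals.std(ddof=0))
            rec[f"{stat}_min"] = float(vals.min())
            rec[f"{stat}_max"] = float(vals.max())
        out.append(rec)
    return pd.DataFrame(out).sort_values(["bin", "diel"]).reset_index(drop=True)


def whale_diel_summary(dives: Sequence[Dive]) -> pd.DataFrame:
    """Per-tag, per-diel pooled summary (the whole-deployment aggregation)."""
    df = dives_to_frame(dives)
    if df.empty:
        return df
    out = []
    for (tag, diel), grp in df.groupby(["tag_id", "diel"], dropna=False):
        rec = {"tag_id": tag, "diel": diel, "n_dives": len(grp)}
        for stat in _STATS:
            vals = grp[stat].dropna().to_numpy(float)
            if vals.size == 0:
                continue
            rec[f"{stat}_mean"] = float(vals.mean())
            rec[f"{stat}_sd"] = float(vals.std(ddof=0))
            rec[f"{stat}_min"] = float(vals.min())
            rec[f"{stat}_max"] = float(vals.max())
        out.append(rec)
    return pd.DataFrame(out)


def read_depth_csv(path: str | Path,
                   resolution_s: float = SAMPLE_SECONDS) -> list[DiveBout]:
    """Read a depth time-series CSV (tag_id, time, depth_m) into bouts.

    Rows are grouped by tag and split into separate bouts wherever the
    sampling interval deviates from the nominal resolution, so gaps never
    hide inside a bout.
    """
    df = pd.read_csv(path, dtype={"tag_id": str})
    need = {"tag_id", "time", "depth_m"}
    if not need.issubset(df.columns):
        raise ValueError(f"depth CSV needs columns {sorted(need)}")
    bouts = []
    for tag, grp in df.groupby("tag_id", sort=True):
        grp = grp.sort_values("time")
        times = [pd.Timestamp(t).to_pydatetime() for t in grp["time"]]
        depths = grp["depth_m"].to_numpy(float)
        ts = np.array([t.timestamp() for t in times])
        brk = np.flatnonzero(~np.isclose(np.diff(ts), resolution_s, atol=1.0))
        bounds = [0, *(int(i) + 1 for i in brk), len(ts)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a >= 2:
                bouts.append(DiveBout(tag_id=str(tag), start=times[a],
                                      depths=depths[a:b],
                                      resolution_s=resolution_s))
    return bouts


def write_depth_csv(bouts: Sequence[DiveBout], path: str | Path) -> None:
    rows = []
    for bout in bouts:
        for t, d in zip(bout.sample_times(), bout.depths):
            rows.append({"tag_id": bout.tag_id, "time": t.isoformat(),
                         "depth_m": d})
    pd.DataFrame(rows).to_csv(path, index=False)
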