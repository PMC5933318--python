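"""Reading, validating, filtering and segmenting raw Argos whale tracks.

Raw Argos locations arrive as delimited text with a tag id, timestamp,
location-quality class (3/2/1/0/A/B) and longitude/latitude.  This module
turns such files into time-ordered :class:`Track` objects, removes
biologically implausible fixes with an iterative neighbour-speed filter,
splits tracks at long transmission gaps (the "whale #2a / #2b"
convention: alphabetic segment suffixes), and computes inclusive track
durations in days.
"""

from __future__ import annotations

import json
import logging
import string
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geo import haversine_km

logger = logging.getLogger(__name__)

LOC_CLASSES = ("3", "2", "1", "0", "A", "B")
#: quality ordering used to break duplicate-timestamp ties (best first)
_CLASS_RANK = {c: i for i, c in enumerate(LOC_CLASSES)}

#: default column mapping, matching a Wildlife Computers Argos export
DEFAULT_FORMAT = {
    "tag_id": "DeployID",
    "time": "Date",
    "loc_class": "Quality",
    "lat": "Latitude",
    "lon": "Longitude",
}

DEFAULT_MAX_SPEED_KMH = 30.0
DEFAULT_GAP_DAYS = 28.0


class FormatError(ValueError):
    """Input file does not match the declared column mapping."""


@dataclass(frozen=True)
class ArgosFix:
    """A single Argos-derived location with its quality class."""

    tag_id: str
    time: datetime
    lon: float
    lat: float
    loc_class: str

    def __post_init__(self):
        if self.loc_class not in LOC_CLASSES:
            raise ValueError(f"unknown Argos location class {self.loc_class!r}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of bounds")
        if self.time.tzinfo is None:
            object.__setattr__(self, "time", self.time.replace(tzinfo=timezone.utc))
        # canonical longitude range [-180, 180)
        lon = ((self.lon + 180.0) % 360.0) - 180.0
        object.__setattr__(self, "lon", lon)


@dataclass
class Track:
    """A time-ordered sequence of fixes from one tag (or tag segment)."""

    track_id: str
    fixes: list[ArgosFix] = field(default_factory=list)

    def __post_init__(self):
        if len(self.fixes) < 2:
            raise ValueError(f"track {self.track_id!r} needs >= 2 fixes")
        times = [f.time for f in self.fixes]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"track {self.track_id!r} fixes not time-ordered")
        tags = {f.tag_id for f in self.fixes}
        if len(tags) > 1:
            raise ValueError(f"track {self.track_id!r} mixes tags {sorted(tags)}")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def start(self) -> datetime:
        return self.fixes[0].time

    @property
    def end(self) -> datetime:
        return self.fixes[-1].time

    @property
    def tag_id(self) -> str:
        return self.fixes[0].tag_id

    def times(self) -> np.ndarray:
        return np.array([f.time.timestamp() for f in self.fixes])

    def lonlat(self) -> np.ndarray:
        return np.array([[f.lon, f.lat] for f in self.fixes])

    def loc_classes(self) -> list[str]:
        return [f.loc_class for f in self.fixes]


def read_argos(path: str | Path,
               format_spec: Mapping[str, str] | None = None) -> list[Track]:
    """Read a delimited Argos location file into one Track per tag.

    Rows are sorted by time; duplicate (tag, time) rows are collapsed,
    keeping the higher-quality location class (first row on ties).
    Unparseable rows are skipped with a logged count.  Tags with a single
    usable fix are dropped with a warning (a Track needs two).
    """
    spec = dict(DEFAULT_FORMAT)
    if format_spec:
        spec.update(format_spec)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [col for col in spec.values() if col not in df.columns]
    if missing and format_spec is None \
            and {"tag_id", "time", "loc_class", "lat", "lon"} <= set(df.columns):
        # fall back to the package's own cleaned/simulated CSV dialect
        spec = {k: k for k in ("tag_id", "time", "loc_class", "lat", "lon")}
        missing = []
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path.name}; "
                          f"have {list(df.columns)}")
    if df.empty:
        logger.warning("no data rows in %s", path.name)
        return []

    fixes: dict[str, list[ArgosFix]] = {}
    n_bad = 0
    for _, row in df.iterrows():
        try:
            t = pd.Timestamp(str(row[spec["time"]]))
            if t.tzinfo is None:
                t = t.tz_localize("UTC")
            fix = ArgosFix(
                tag_id=str(row[spec["tag_id"]]),
                time=t.to_pydatetime(),
                lon=float(row[spec["lon"]]),
                lat=float(row[spec["lat"]]),
                loc_class=str(row[spec["loc_class"]]).strip(),
            )
        except (ValueError, TypeError):
            n_bad += 1
            continue
        fixes.setdefault(fix.tag_id, []).append(fix)
    if n_bad:
        logger.warning("skipped %d unparseable row(s) in %s", n_bad, path.name)

    tracks = []
    for tag_id in sorted(fixes):
        rows = sorted(fixes[tag_id],
                      key=lambda f: (f.time, _CLASS_RANK[f.loc_class]))
        deduped = []
        for f in rows:
            if deduped and f.time == deduped[-1].time:
                continue  # keep first = best class at this timestamp
            deduped.append(f)
        if len(deduped) < 2:
            logger.warning("tag %s has < 2 usable fixes; dropped", tag_id)
            continue
        tracks.append(Track(track_id=tag_id, fixes=deduped))
    return tracks


def _neighbor_speeds(track: Track) -> np.ndarray:
    """Implied speed (km/h) of each fix to its temporal neighbours.

    Interior fixes get the minimum of the speeds to the previous and next
    fix; endpoints get the speed to their sole neighbour.  Zero time gaps
    imply infinite speed.
    """
    xy = track.lonlat()
    t = track.times()
    d = haversine_km(xy[:-1, 0], xy[:-1, 1], xy[1:, 0], xy[1:, 1])
    dt_h = np.diff(t) / 3600.0
    with np.errstate(divide="ignore", invalid="ignore"):
        seg = np.where(dt_h > 0, d / np.where(dt_h > 0, dt_h, 1.0), np.inf)
    n = len(track)
    speeds = np.empty(n)
    speeds[0] = seg[0]
    speeds[-1] = seg[-1]
    if n > 2:
        speeds[1:-1] = np.minimum(seg[:-1], seg[1:])
    return speeds


def filter_implausible(track: Track,
                       max_speed: float = DEFAULT_MAX_SPEED_KMH,
                       max_fraction_removed: float = 0.04) -> Track:
    """Iteratively remove fixes that imply impossible swimming speeds.

    A fix is implausible when even the slower of its two neighbour speeds
    exceeds ``max_speed`` km/h (endpoints: the speed to their only
    neighbour).  The worst offender is removed and speeds recomputed until
    no fix exceeds the threshold.  Warns, but does not fail, when the
    removed fraction exceeds ``max_fraction_removed``.
    """
    if max_speed <= 0:
        raise ValueError("max_speed must be positive")
    kept = list(track.fixes)
    n0 = len(kept)
    while len(kept) > 2:
        cur = Track(track_id=track.track_id, fixes=kept)
        speeds = _neighbor_speeds(cur)
        if speeds.max() <= max_speed:
            break
        # remove the worst offender; on ties prefer an interior fix (the
        # spike itself), not the endpoints it drags along
        worst = int(np.argmax(speeds))
        interior = np.argmax(speeds[1:-1]) + 1 if len(kept) > 2 else worst
        if speeds[interior] == speeds[worst]:
            worst = int(interior)
        kept.pop(worst)
    frac = (n0 - len(kept)) / n0
    if frac > max_fraction_removed:
        logger.warning("track %s: removed %.1f%% of fixes (> %.1f%%); "
                       "check data quality", track.track_id, 100 * frac,
                       100 * max_fraction_removed)
    if len(kept) == n0:
        return track
    return Track(track_id=track.track_id, fixes=kept)


def split_on_gap(track: Track, gap_days: float = DEFAULT_GAP_DAYS) -> list[Track]:
    """Cut a track at every transmission gap longer than ``gap_days``.

    Segments get alphabetic suffixes ("a", "b", ...) in temporal order;
    if no gap exceeds the threshold the original track is returned with
    its id unchanged.  Segments left with fewer than 2 fixes are dropped
    with a warning.
    """
    if gap_days <= 0:
        raise ValueError("gap_days must be positive")
    t = track.times()
    cut_after = np.where(np.diff(t) > gap_days * 86400.0)[0]
    if cut_after.size == 0:
        return [track]
    bounds = [0, *(int(i) + 1 for i in cut_after), len(track)]
    segments = []
    for k, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        part = track.fixes[a:b]
        if len(part) < 2:
            logger.warning("track %s: segment %d has < 2 fixes; dropped",
                           track.track_id, k)
            continue
        segments.append(part)
    out = []
    for k, part in enumerate(segments):
        suffix = string.ascii_lowercase[k]
        out.append(Track(track_id=f"{track.track_id}{suffix}", fixes=part))
    return out


def track_duration(track_or_start, end: datetime | None = None) -> int:
    """Inclusive duration in days: (end date - start date) + 1.

    Both endpoint calendar dates count, so a track starting and ending on
    the same date has duration 1.
    """
    if end is None:
        start, end = track_or_start.start, track_or_start.end
    else:
        start = track_or_start
    d0 = start.date() if isinstance(start, datetime) else start
    d1 = end.date() if isinstance(end, datetime) else end
    if d1 < d0:
        raise ValueError(f"end {end} before start {start}")
    return (d1 - d0).days + 1


def prepare_tracks(tracks: Iterable[Track],
                   max_speed: float = DEFAULT_MAX_SPEED_KMH,
                   gap_days: float = DEFAULT_GAP_DAYS) -> list[Track]:
    """Filter then gap-split a collection of tracks (the `prepare` stage)."""
    out: list[Track] = []
    for tr in tracks:
        out.extend(split_on_gap(filter_implausible(tr, max_speed), gap_days))
    return out


def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    rows = [
        {"track_id": tr.track_id, "tag_id": f.tag_id,
         "time": f.time.isoformat(), "lon": f.lon, "lat": f.lat,
         "loc_class": f.loc_class}
        for tr in tracks for f in tr.fixes
    ]
    return pd.DataFrame(rows, columns=["track_id", "tag_id", "time",
                                       "lon", "lat", "loc_class"])


def write_tracks_csv(tracks: Sequence[Track], path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def write_track_geojson(track: Track, path: str | Path) -> None:
    """One GeoJSON Feature per track: a LineString of its fixes."""
    feature = {
        "type": "Feature",
        "properties": {"track_id": track.track_id,
                       "start": track.start.isoformat(),
                       "end": track.end.isoformat(),
                       "n_fixes": len(track)},
        "geometry": {
            "type": "LineString",
            "coordinates": [[f.lon, f.lat] for f in track.fixes],
        },
    }
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": [feature]}, indent=2))


def read_tracks_csv(path: str | Path) -> list[Track]:
    """Read the cleaned-track CSV dialect written by :func:`write_tracks_csv`."""
    df = pd.read_csv(path, dtype={"track_id": str, "tag_id": str,
                                  "loc_class": str})
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        fixes = [ArgosFix(tag_id=str(r.tag_id),
                          time=pd.Timestamp(r.time).to_pydatetime(),
                          lon=float(r.lon), lat=float(r.lat),
                          loc_class=str(r.loc_class))
                 for r in grp.itertuples()]
        fixes.sort(key=lambda f: f.time)
        tracks.append(Track(track_id=str(tid), fixes=fixes))
    return tracks
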