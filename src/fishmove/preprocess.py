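"""Raw tag records -> trimmed, filtered, log-transformed movement paths.

Two daily movement metrics are built per fish:

* **net vertical movement** (m/day): the sum of absolute differences between
  consecutive 10-minute depth readings within a UTC day; only complete days
  (144 samples) qualify;
* **horizontal step length** (m/day): the great-circle distance between
  consecutive daily geolocation estimates, stamped to the earlier day so that
  day *t*'s horizontal and vertical metrics describe the same 24 h.

Both metrics are floored at a small positive rate and natural-log transformed.
The first two weeks and the last day of each aligned series are discarded
(release/recapture artefacts) and fish with fewer than 40 remaining days, or
with incomplete depth coverage on any remaining day, are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import (
    SAMPLES_PER_DAY,
    DataError,
    DepthSeries,
    FishMetadata,
    GeolocationTrack,
    MovementPath,
    UsageError,
)

#: Mean Earth radius (m) used by the great-circle (haversine) distance.
EARTH_RADIUS_M = 6_371_000.0


@dataclass
class PreprocessConfig:
    trim_head_days: int = 14
    trim_tail_days: int = 1
    min_days: int = 40
    zero_floor: float = 1.0  # m/day; keeps the log transform finite

    def __post_init__(self) -> None:
        if min(self.trim_head_days, self.trim_tail_days) < 0 or self.min_days < 1:
            raise UsageError("trim days must be >= 0 and min_days >= 1")
        if self.zero_floor <= 0:
            raise UsageError("zero_floor must be positive")


@dataclass
class Rejection:
    """Typed refusal to build a path: reason is 'too_short' or 'incomplete_depth'."""

    fish_id: str
    reason: str
    detail: str = ""


def daily_vertical_movement(d: DepthSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-day net vertical movement for complete days.

    Returns ``(dates, values, incomplete_dates)`` where values[i] is the sum of
    |depth_{k+1} - depth_k| over the 143 consecutive within-day sample pairs of
    dates[i]. Days with fewer or more than 144 samples are excluded and
    reported in ``incomplete_dates``.
    """
    days = d.timestamps.astype("datetime64[D]")
    uniq, start = np.unique(days, return_index=True)
    counts = np.diff(np.append(start, days.size))
    complete = counts == SAMPLES_PER_DAY
    values = np.empty(int(complete.sum()))
    out_i = 0
    for i in np.flatnonzero(complete):
        seg = d.depths[start[i] : start[i] + counts[i]]
        values[out_i] = np.abs(np.diff(seg)).sum()
        out_i += 1
    return uniq[complete], values, uniq[~complete]


def great_circle_m(a, b) -> float | np.ndarray:
    """Haversine great-circle distance in metres between (lat, lon) pairs.

    Accepts scalars or arrays (broadcast); symmetric and antipodal-safe.
    """
    lat1, lon1 = np.radians(np.asarray(a[0], float)), np.radians(np.asarray(a[1], float))
    lat2, lon2 = np.radians(np.asarray(b[0], float)), np.radians(np.asarray(b[1], float))
    if np.any(np.abs([a[0]]) > 90) or np.any(np.abs([b[0]]) > 90):
        raise DataError("latitude outside [-90, 90]")
    s = (
        np.sin(0.5 * (lat2 - lat1)) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin(0.5 * (lon2 - lon1)) ** 2
    )
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.minimum(1.0, np.sqrt(s)))


def daily_step_lengths(t: GeolocationTrack) -> tuple[np.ndarray, np.ndarray]:
    """Daily step lengths (m/day) stamped to the earlier day.

    Consecutive calendar days only: where the track skips a day, no step is
    produced for the earlier day. Returns ``(dates, steps)``.
    """
    if len(t) < 2:
        raise UsageError(f"{t.fish_id}: need at least 2 positions")
    gaps = np.diff(t.dates).astype(int)
    keep = gaps == 1
    d = great_circle_m((t.lat[:-1], t.lon[:-1]), (t.lat[1:], t.lon[1:]))
    return t.dates[:-1][keep], np.atleast_1d(d)[keep]


def build_movement_path(
    d: DepthSeries,
    t: GeolocationTrack,
    meta: FishMetadata,
    cfg: PreprocessConfig | None = None,
) -> MovementPath | Rejection:
    """Assemble one fish's bivariate log-movement path, or reject it.

    Days present in both the vertical and horizontal series are aligned, the
    first ``trim_head_days`` and last ``trim_tail_days`` aligned days dropped,
    raw rates floored at ``zero_floor`` and natural-log transformed. Fish are
    rejected (typed ``Rejection``) when an incomplete depth day survives the
    trim or fewer than ``min_days`` days remain.
    """
    cfg = cfg or PreprocessConfig()
    if not (d.fish_id == t.fish_id == meta.fish_id):
        raise UsageError(
            f"id mismatch: depth={d.fish_id} track={t.fish_id} meta={meta.fish_id}"
        )
    vdates, vvals, incomplete = daily_vertical_movement(d)
    hdates, hvals = daily_step_lengths(t)

    common, vi, hi = np.intersect1d(vdates, hdates, return_indices=True)
    lo, hi_ = cfg.trim_head_days, common.size - cfg.trim_tail_days
    if hi_ <= lo:
        return Rejection(meta.fish_id, "too_short", f"{common.size} aligned days")
    sel = slice(lo, hi_)
    kept_dates = common[sel]

    # an incomplete depth day anywhere inside the retained window disqualifies
    in_window = (incomplete >= kept_dates[0]) & (incomplete <= kept_dates[-1])
    if np.any(in_window):
        return Rejection(meta.fish_id, "incomplete_depth")
    if kept_dates.size < cfg.min_days:
        return Rejection(
            meta.fish_id, "too_short", f"{kept_dates.size} days < {cfg.min_days}"
        )

    h_raw = np.maximum(hvals[hi][sel], cfg.zero_floor)
    v_raw = np.maximum(vvals[vi][sel], cfg.zero_floor)
    ti = np.searchsorted(t.dates, kept_dates)
    return MovementPath(
        meta.fish_id,
        meta.species,
        meta.substock,
        kept_dates,
        np.log(h_raw),
        np.log(v_raw),
        t.lat[ti],
        t.lon[ti],
    )
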