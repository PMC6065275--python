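"""Core record types and CSV input/output.

The pipeline consumes three raw inputs per tagged fish — a 10-minute depth
series from the data storage tag, daily geolocation estimates, and release
metadata — and emits decoded state sequences plus derived movement paths.
All formats are plain comma-separated UTF-8 with "." decimals and ISO dates;
a "day" is midnight-to-midnight UTC.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SPECIES = ("cod", "plaice")

#: Declared substock catalogue (release-location groupings) per species.
SUBSTOCKS: Mapping[str, tuple[str, ...]] = {
    "cod": ("southern_north_sea", "english_channel"),
    "plaice": ("central_north_sea", "german_bight", "southern_north_sea"),
}

#: Nominal tag sampling interval (seconds) and samples per complete day.
SAMPLE_INTERVAL_S = 600
SAMPLES_PER_DAY = 144


class FishmoveError(Exception):
    """Base class for all package errors."""


class FormatError(FishmoveError):
    """A file does not have the expected layout (missing columns, bad header)."""


class DataError(FishmoveError):
    """A record violates a data invariant (named with its source row)."""


class UsageError(FishmoveError):
    """The caller combined arguments incorrectly."""


class StateError(FishmoveError):
    """An object is not in the state the operation requires."""


class PipelineError(FishmoveError):
    """A whole-cohort stage cannot proceed (e.g. empty selection)."""


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass
class DepthSeries:
    """One fish's 10-minute depth record.

    ``timestamps`` are strictly increasing UTC datetimes; nominal spacing is
    600 s and deviations are flagged, not repaired. Depths are metres below
    surface and non-negative.
    """

    fish_id: str
    timestamps: np.ndarray  # datetime64[s]
    depths: np.ndarray  # float metres, >= 0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.depths = np.asarray(self.depths, dtype=float)
        if self.timestamps.shape != self.depths.shape:
            raise DataError(f"{self.fish_id}: timestamps/depths length mismatch")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps).astype(int) > 0):
            raise DataError(f"{self.fish_id}: timestamps not strictly increasing")
        if np.any(self.depths < 0):
            raise DataError(f"{self.fish_id}: negative depth")

    def __len__(self) -> int:
        return self.timestamps.size

    def gap_mask(self) -> np.ndarray:
        """Boolean mask over intervals: True where spacing deviates from 600 s."""
        if len(self) < 2:
            return np.zeros(0, dtype=bool)
        return np.diff(self.timestamps).astype(int) != SAMPLE_INTERVAL_S


@dataclass
class GeolocationTrack:
    """Daily geolocation estimates (decimal degrees, WGS84) for one fish."""

    fish_id: str
    dates: np.ndarray  # datetime64[D], strictly increasing
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        n = self.dates.size
        if self.lat.size != n or self.lon.size != n:
            raise DataError(f"{self.fish_id}: dates/lat/lon length mismatch")
        if n > 1 and not np.all(np.diff(self.dates).astype(int) > 0):
            raise DataError(f"{self.fish_id}: dates not strictly increasing (or duplicated)")
        if np.any(np.abs(self.lat) > 90.0):
            raise DataError(f"{self.fish_id}: latitude outside [-90, 90]")
        if np.any(np.abs(self.lon) > 180.0):
            raise DataError(f"{self.fish_id}: longitude outside [-180, 180]")

    def __len__(self) -> int:
        return self.dates.size


@dataclass
class FishMetadata:
    fish_id: str
    species: str
    substock: str
    release_date: np.datetime64
    end_date: np.datetime64

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise DataError(f"{self.fish_id}: unknown species {self.species!r}")
        if self.substock not in SUBSTOCKS[self.species]:
            raise DataError(
                f"{self.fish_id}: substock {self.substock!r} not in catalogue for {self.species}"
            )
        self.release_date = np.datetime64(self.release_date, "D")
        self.end_date = np.datetime64(self.end_date, "D")
        if not self.release_date < self.end_date:
            raise DataError(f"{self.fish_id}: release_date must precede end_date")


@dataclass
class MovementPath:
    """A fish's dated bivariate log-movement series with daily positions.

    ``h`` and ``v`` are natural logs of horizontal (step length) and vertical
    (net vertical movement) rates in m/day; the pair (h_t, v_t) is the daily
    observation fed to the hidden Markov model.
    """

    fish_id: str
    species: str
    substock: str
    dates: np.ndarray  # datetime64[D]
    h: np.ndarray  # log horizontal movement
    v: np.ndarray  # log vertical movement
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        for name in ("h", "v", "lat", "lon"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size != self.dates.size:
                raise DataError(f"{self.fish_id}: {name} length != dates length")
        if not (np.all(np.isfinite(self.h)) and np.all(np.isfinite(self.v))):
            raise DataError(f"{self.fish_id}: non-finite log-movement values")

    def __len__(self) -> int:
        return self.dates.size

    @property
    def x(self) -> np.ndarray:
        """(T, 2) observation matrix, columns (h, v)."""
        return np.column_stack([self.h, self.v])


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_depth_csv(path) -> dict[str, DepthSeries]:
    """Read a depth CSV (fish_id,timestamp,depth_m) into per-fish series.

    Rows may be interleaved across fish and unsorted; each returned series is
    time-sorted. Malformed rows are reported with their line number (header is
    line 1).
    """
    df = pd.read_csv(path, dtype={"fish_id": str})
    _require_columns(df, ("fish_id", "timestamp", "depth_m"), path)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        raise DataError(f"{path}: unparseable timestamp at line {bad[0] + 2}")
    depth = pd.to_numeric(df["depth_m"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(depth.to_numpy()))
    if bad.size:
        raise DataError(f"{path}: non-numeric depth at line {bad[0] + 2}")
    bad = np.flatnonzero((depth < 0).to_numpy())
    if bad.size:
        raise DataError(f"{path}: negative depth at line {bad[0] + 2}")
    df = df.assign(_ts=ts.dt.tz_localize(None), _depth=depth)
    out: dict[str, DepthSeries] = {}
    for fid, grp in df.groupby("fish_id", sort=True):
        grp = grp.sort_values("_ts")
        t = grp["_ts"].to_numpy(dtype="datetime64[s]")
        if t.size > 1 and np.any(np.diff(t).astype(int) <= 0):
            raise DataError(f"{path}: duplicate timestamp for fish {fid}")
        out[str(fid)] = DepthSeries(str(fid), t, grp["_depth"].to_numpy())
    return out


def read_track_csv(path) -> dict[str, GeolocationTrack]:
    """Read a geolocation CSV (fish_id,date,lat,lon) into per-fish daily tracks."""
    df = pd.read_csv(path, dtype={"fish_id": str})
    _require_columns(df, ("fish_id", "date", "lat", "lon"), path)
    dates = pd.to_datetime(df["date"], errors="coerce")
    bad = np.flatnonzero(dates.isna().to_numpy())
    if bad.size:
        raise DataError(f"{path}: unparseable date at line {bad[0] + 2}")
    df = df.assign(_date=dates.dt.floor("D"))
    dup = df.duplicated(subset=["fish_id", "_date"], keep=False)
    if dup.any():
        raise DataError(f"{path}: duplicate (fish_id, date) at line {np.flatnonzero(dup)[0] + 2}")
    out: dict[str, GeolocationTrack] = {}
    for fid, grp in df.groupby("fish_id", sort=True):
        grp = grp.sort_values("_date")
        out[str(fid)] = GeolocationTrack(
            str(fid),
            grp["_date"].to_numpy(dtype="datetime64[D]"),
            grp["lat"].to_numpy(dtype=float),
            grp["lon"].to_numpy(dtype=float),
        )
    return out


def read_metadata_csv(path) -> dict[str, FishMetadata]:
    df = pd.read_csv(path, dtype={"fish_id": str})
    _require_columns(df, ("fish_id", "species", "substock", "release_date", "end_date"), path)
    out = {}
    for _, row in df.iterrows():
        out[str(row["fish_id"])] = FishMetadata(
            str(row["fish_id"]),
            str(row["species"]),
            str(row["substock"]),
            np.datetime64(str(row["release_date"]), "D"),
            np.datetime64(str(row["end_date"]), "D"),
        )
    return out


# ---------------------------------------------------------------------------
# Movement-path CSV (preprocessing output)
# ---------------------------------------------------------------------------

_PATH_COLS = ["fish_id", "species", "substock", "date", "lat", "lon", "h_log", "v_log"]


def write_path_csv(paths: Iterable[MovementPath], out_path, manifest: dict | None = None) -> None:
    frames = []
    for p in paths:
        frames.append(
            pd.DataFrame(
                {
                    "fish_id": p.fish_id,
                    "species": p.species,
                    "substock": p.substock,
                    "date": p.dates.astype(str),
                    "lat": p.lat,
                    "lon": p.lon,
                    "h_log": p.h,
                    "v_log": p.v,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_PATH_COLS)
    df.to_csv(out_path, index=False, float_format="%.6f")
    if manifest is not None:
        write_manifest(out_path, manifest)


def read_path_csv(path) -> list[MovementPath]:
    df = pd.read_csv(path, dtype={"fish_id": str})
    _require_columns(df, _PATH_COLS, path)
    out = []
    for fid, grp in df.groupby("fish_id", sort=True):
        grp = grp.sort_values("date")
        out.append(
            MovementPath(
                str(fid),
                str(grp["species"].iloc[0]),
                str(grp["substock"].iloc[0]),
                grp["date"].to_numpy(dtype="datetime64[D]"),
                grp["h_log"].to_numpy(dtype=float),
                grp["v_log"].to_numpy(dtype=float),
                grp["lat"].to_numpy(dtype=float),
                grp["lon"].to_numpy(dtype=float),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Decoded-state CSV (pipeline output)
# ---------------------------------------------------------------------------

STATE_LABELS = ("R", "M")

_STATE_COLS = ["fish_id", "date", "lat", "lon", "p_resident", "state", "uncertain"]


def write_state_csv(fits, out_path, manifest: dict | None = None) -> None:
    """Write decoded state sequences: one row per fish-day.

    Columns: fish_id,date,lat,lon,p_resident,state,uncertain. ``state`` is
    "R"/"M"; ``uncertain`` is true where the winning smoothed probability is
    below the classification-uncertainty threshold (0.85). Probabilities are
    written to 6 decimals and round-trip at that precision.
    """
    frames = []
    for fit in fits:
        if fit.smoothed is None or fit.states is None:
            raise StateError(f"{fit.path.fish_id}: fit has not been decoded")
        p = fit.path
        frames.append(
            pd.DataFrame(
                {
                    "fish_id": p.fish_id,
                    "date": p.dates.astype(str),
                    "lat": p.lat,
                    "lon": p.lon,
                    "p_resident": fit.smoothed[:, 0],
                    "state": np.asarray(STATE_LABELS)[fit.states],
                    "uncertain": fit.uncertain.astype(bool),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_STATE_COLS)
    df.to_csv(out_path, index=False, float_format="%.6f")
    if manifest is not None:
        write_manifest(out_path, manifest)


def read_state_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"fish_id": str})
    _require_columns(df, _STATE_COLS, path)
    df["date"] = pd.to_datetime(df["date"])
    if not df["state"].isin(STATE_LABELS).all():
        raise DataError(f"{path}: state labels must be one of {STATE_LABELS}")
    return df


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping (order-insensitive)."""
    import json

    canon = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(target_path, manifest: dict) -> None:
    """Write a ``<target>.manifest.txt`` sidecar recording run provenance."""
    from fishmove import __version__

    lines = [f"fishmove_version: {__version__}"]
    for k in sorted(manifest):
        lines.append(f"{k}: {manifest[k]}")
    with open(str(target_path) + ".manifest.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")
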