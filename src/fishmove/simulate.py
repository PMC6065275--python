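"""Synthetic tagged-fish cohorts with known truth.

Generates Markov-switching bivariate lognormal daily movement series with
per-fish parameter heterogeneity, consistent geolocation tracks (so the
horizontal metric survives a round trip through the step-length computation)
and optional 10-minute depth series (likewise for the vertical metric),
mirroring the mixed data-rich / data-poor structure of archival-tag cohorts.

Default movement scales are anchored to published state-dependent rates for
North Sea cod and plaice (resident horizontal on the order of 6-9 km/day,
migrating 13-14 km/day; vertical tens vs low hundreds of m/day) so synthetic
cohorts are numerically plausible — an emulation, not a replication, of any
particular dataset. All randomness flows through one seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import MIGRATING, RESIDENT, HMMParameters
from .io import (
    SAMPLES_PER_DAY,
    SUBSTOCKS,
    DepthSeries,
    FishMetadata,
    GeolocationTrack,
    MovementPath,
)
from .population import week_of_year
from .preprocess import EARTH_RADIUS_M


@dataclass
class SeasonalSwitching:
    """Calendar-driven transition-matrix toggle producing an annual cycle.

    Inside ``resident_weeks`` (inclusive, wrapping allowed) the chain uses
    (gamma_rr, gamma_mm) = ``in_season``; outside it, ``out_season``. The
    defaults make the dominant state flip within a few days of the switch.
    """

    resident_weeks: tuple[int, int] = (23, 43)  # approx June - October
    in_season: tuple[float, float] = (0.99, 0.75)
    out_season: tuple[float, float] = (0.75, 0.99)


@dataclass
class SpeciesSpec:
    """Hyper-distribution of per-fish model parameters for one species.

    ``mu_hyper_mean``/``mu_hyper_sd`` are (2, 2) [state, dim] on the log
    scale; per-fish state means are Gaussian draws (redrawn until the
    resident horizontal mean is below the migrating one, the identifiability
    convention). Sigmas are uniform on [sigma_low, sigma_high], correlations
    uniform on [rho_low, rho_high]; self-transitions are Beta(gamma_alpha,
    gamma_beta) draws unless ``gamma_fixed`` pins them.
    """

    name: str = "cod"
    mu_hyper_mean: np.ndarray = field(
        default_factory=lambda: np.array([[9.13, 3.45], [9.54, 5.06]])
    )
    mu_hyper_sd: np.ndarray = field(default_factory=lambda: np.full((2, 2), 0.15))
    sigma_low: float = 0.45
    sigma_high: float = 0.65
    rho_low: float = 0.0
    rho_high: float = 0.3
    gamma_alpha: float = 99.0
    gamma_beta: float = 1.0
    gamma_fixed: float | None = None
    seasonal: SeasonalSwitching | None = None

    def __post_init__(self) -> None:
        self.mu_hyper_mean = np.asarray(self.mu_hyper_mean, float).reshape(2, 2)
        self.mu_hyper_sd = np.asarray(self.mu_hyper_sd, float).reshape(2, 2)
        if not self.mu_hyper_mean[RESIDENT, 0] < self.mu_hyper_mean[MIGRATING, 0]:
            raise ValueError("resident horizontal hyper-mean must be below migrating")
        if np.any(self.mu_hyper_sd < 0) or self.sigma_low <= 0:
            raise ValueError("negative hyper-sd or non-positive sigma bound")

    @classmethod
    def cod(cls, **kw) -> "SpeciesSpec":
        """Cod-like scales: resident ~9.2 km/day / ~32 m/day; migrating
        ~13.9 km/day / ~158 m/day."""
        return cls(name="cod", **kw)

    @classmethod
    def plaice(cls, **kw) -> "SpeciesSpec":
        """Plaice-like scales: resident ~6.5 km/day / ~20 m/day; migrating
        ~13 km/day / ~120 m/day."""
        return cls(
            name="plaice",
            mu_hyper_mean=np.array([[8.78, 3.00], [9.47, 4.79]]),
            **kw,
        )

    @classmethod
    def well_separated(cls, name: str = "cod") -> "SpeciesSpec":
        """Sharply separated states (means (2,2) vs (4,4), sigma 0.5, rho 0,
        gamma_jj fixed at 0.99, no heterogeneity) for recovery harnesses."""
        return cls(
            name=name,
            mu_hyper_mean=np.array([[2.0, 2.0], [4.0, 4.0]]),
            mu_hyper_sd=np.zeros((2, 2)),
            sigma_low=0.5,
            sigma_high=0.5,
            rho_low=0.0,
            rho_high=0.0,
            gamma_fixed=0.99,
        )


@dataclass
class CohortSpec:
    """Cohort composition: counts and track-length ranges, seeded."""

    n_rich: int = 34
    n_poor: int = 73
    t_rich: tuple[int, int] = (200, 600)
    t_poor: tuple[int, int] = (40, 80)
    seed: int = 0
    start_date_range: tuple[str, str] = ("2003-06-01", "2004-05-31")
    release_box: tuple[float, float, float, float] = (52.0, 56.0, 0.0, 4.0)  # lat, lat, lon, lon
    #: extra leading/trailing days simulated so downstream trimming
    #: (release/recapture exclusion) still leaves the nominal track length
    margin_days: int = 0

    def __post_init__(self) -> None:
        if self.n_rich + self.n_poor < 1:
            raise ValueError("cohort must contain at least one fish")
        for lo, hi in (self.t_rich, self.t_poor):
            if not (1 <= lo <= hi <= 1000):
                raise ValueError("track-length ranges must lie within [1, 1000]")


@dataclass
class SimulatedFish:
    """One simulated fish: its path, the generating truth, and raw records."""

    path: MovementPath
    states: np.ndarray  # true S_t
    params: HMMParameters  # true per-fish parameters
    metadata: FishMetadata
    track: GeolocationTrack
    depth: DepthSeries | None = None
    rich: bool = False


# ---------------------------------------------------------------------------
# Individual simulation
# ---------------------------------------------------------------------------


def _draw_params(sp: SpeciesSpec, rng: np.random.Generator) -> HMMParameters:
    for _ in range(200):
        mu = rng.normal(sp.mu_hyper_mean, sp.mu_hyper_sd)
        if mu[RESIDENT, 0] < mu[MIGRATING, 0]:
            break
    else:
        mu = sp.mu_hyper_mean.copy()
    sigma = rng.uniform(sp.sigma_low, sp.sigma_high, (2, 2))
    rho = rng.uniform(sp.rho_low, sp.rho_high, 2)
    if sp.gamma_fixed is not None:
        g = np.array([sp.gamma_fixed, sp.gamma_fixed])
    else:
        g = np.clip(rng.beta(sp.gamma_alpha, sp.gamma_beta, 2), 0.5, 0.9999)
    return HMMParameters(float(g[0]), float(g[1]), mu, sigma, rho)


def simulate_individual(
    sp: SpeciesSpec,
    T: int,
    seed: int,
    start_date: str | np.datetime64 = "2004-01-01",
    origin: tuple[float, float] = (54.0, 2.0),
    fish_id: str = "sim",
    substock: str | None = None,
) -> SimulatedFish:
    """Simulate one fish: parameters, state chain, emissions, track.

    S_1 is uniform; S_{t+1} | S_t follows the per-fish transition matrix (or
    the seasonal toggle when the species spec has one); x_t | S_t = j is
    MVN(mu_j, Sigma_j). Deterministic given ``seed``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    params = _draw_params(sp, rng)
    dates = np.datetime64(start_date, "D") + np.arange(T)
    weeks = week_of_year(dates)

    if sp.seasonal is not None:
        lo, hi = sp.seasonal.resident_weeks
        in_season = (
            (weeks >= lo) & (weeks <= hi) if lo <= hi else (weeks >= lo) | (weeks <= hi)
        )
        g_rr = np.where(in_season, sp.seasonal.in_season[0], sp.seasonal.out_season[0])
        g_mm = np.where(in_season, sp.seasonal.in_season[1], sp.seasonal.out_season[1])
    else:
        g_rr = np.full(T, params.gamma_rr)
        g_mm = np.full(T, params.gamma_mm)

    states = np.empty(T, dtype=np.int8)
    states[0] = rng.integers(0, 2)
    u = rng.random(T)
    for t in range(1, T):
        stay = g_rr[t - 1] if states[t - 1] == RESIDENT else g_mm[t - 1]
        states[t] = states[t - 1] if u[t] < stay else 1 - states[t - 1]

    x = np.empty((T, 2))
    for j in (RESIDENT, MIGRATING):
        m = states == j
        n = int(m.sum())
        if n:
            z = rng.standard_normal((n, 2))
            L = np.linalg.cholesky(params.covariance(j))
            x[m] = params.mu[j] + z @ L.T

    species = sp.name
    substock = substock or SUBSTOCKS[species][int(rng.integers(len(SUBSTOCKS[species])))]
    track = _simulate_track_arrays(x[:, 0], states, dates, origin, rng, fish_id)
    path = MovementPath(
        fish_id, species, substock, dates, x[:, 0], x[:, 1],
        track.lat[:-1], track.lon[:-1],
    )
    meta = FishMetadata(fish_id, species, substock, dates[0], dates[-1] + 1)
    return SimulatedFish(path, states, params, meta, track)


# ---------------------------------------------------------------------------
# Track simulation (inverse of the step-length computation)
# ---------------------------------------------------------------------------


def _simulate_track_arrays(h, states, dates, origin, rng, fish_id="sim") -> GeolocationTrack:
    T = h.size
    lat = np.empty(T + 1)
    lon = np.empty(T + 1)
    lat[0], lon[0] = origin
    if not (abs(lat[0]) <= 90 and abs(lon[0]) <= 180):
        raise ValueError("origin outside valid lat/lon")
    heading = rng.uniform(0.0, 2.0 * math.pi)
    deg = 180.0 / math.pi
    for t in range(T):
        if states[t] == RESIDENT:
            heading = rng.uniform(0.0, 2.0 * math.pi)
        else:  # correlated wrapped-normal increments while migrating
            heading += rng.normal(0.0, 0.4)
        d = math.exp(h[t])
        dlat = d * math.cos(heading) / EARTH_RADIUS_M * deg
        lat_next = lat[t] + dlat
        if abs(lat_next) > 85.0:  # keep tracks away from the poles
            heading += math.pi
            dlat = -dlat
            lat_next = lat[t] + dlat
        mid = math.radians(0.5 * (lat[t] + lat_next))
        lon[t + 1] = lon[t] + d * math.sin(heading) / (EARTH_RADIUS_M * math.cos(mid)) * deg
        lat[t + 1] = lat_next
    track_dates = np.append(dates, dates[-1] + 1)
    return GeolocationTrack(fish_id, track_dates, lat, lon)


def simulate_track(
    fish: SimulatedFish, origin: tuple[float, float], seed: int
) -> GeolocationTrack:
    """Re-simulate a consistent geolocation track for an existing fish.

    Daily displacement is exp(h_t) metres; headings are uniform per day while
    resident and correlated while migrating. Dead reckoning uses a mid-latitude
    tangent-plane step, so running the result back through the step-length
    computation recovers exp(h_t) to well within 0.1%.
    """
    rng = np.random.default_rng(seed)
    t = _simulate_track_arrays(fish.path.h, fish.states, fish.path.dates, origin, rng)
    t.fish_id = fish.path.fish_id
    return t


# ---------------------------------------------------------------------------
# Depth simulation (inverse of the vertical-activity sum)
# ---------------------------------------------------------------------------


def simulate_depth(fish: SimulatedFish, seed: int, seabed_m: float = 200.0) -> DepthSeries:
    """10-minute depth series whose per-day activity matches the truth.

    Each day gets 144 samples; the 143 within-day absolute increments are
    drawn half-normal and rescaled to sum exactly to exp(v_t), then signs are
    chosen to keep the walk inside [0, seabed]. Running the result through
    the daily vertical-movement sum recovers exp(v_t) to float precision.
    """
    rng = np.random.default_rng(seed)
    T = len(fish.path)
    n_inc = SAMPLES_PER_DAY - 1
    depths = np.empty(T * SAMPLES_PER_DAY)
    z = seabed_m / 2.0
    for t in range(T):
        target = math.exp(fish.path.v[t])
        for _ in range(20):
            raw = np.abs(rng.standard_normal(n_inc)) + 1e-3
            inc = raw * (target / raw.sum())
            if inc.max() < 0.9 * seabed_m:
                break
        day = np.empty(SAMPLES_PER_DAY)
        day[0] = z
        for k in range(n_inc):
            step = inc[k]
            if z + step > seabed_m:
                sgn = -1.0
            elif z - step < 0.0:
                sgn = 1.0
            else:
                sgn = 1.0 if rng.random() < 0.5 else -1.0
            z += sgn * step
            day[k + 1] = z
        depths[t * SAMPLES_PER_DAY : (t + 1) * SAMPLES_PER_DAY] = day
    base = fish.path.dates.astype("datetime64[s]")
    offsets = (np.arange(SAMPLES_PER_DAY) * 600).astype("timedelta64[s]")
    ts = (base[:, None] + offsets[None, :]).ravel()
    return DepthSeries(fish.path.fish_id, ts, depths)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def simulate_cohort(
    c: CohortSpec, sp: SpeciesSpec, include_depth: bool = False
) -> list[SimulatedFish]:
    """Simulate ``n_rich`` long and ``n_poor`` short fish, reproducibly."""
    rng = np.random.default_rng(c.seed)
    start_lo = np.datetime64(c.start_date_range[0], "D")
    start_hi = np.datetime64(c.start_date_range[1], "D")
    span = int((start_hi - start_lo).astype(int)) + 1
    fishes = []
    specs = [(True, c.t_rich)] * c.n_rich + [(False, c.t_poor)] * c.n_poor
    for i, (rich, trange) in enumerate(specs):
        T = int(rng.integers(trange[0], trange[1] + 1)) + c.margin_days
        fid = f"{sp.name}_{'r' if rich else 'p'}{i:03d}"
        origin = (
            float(rng.uniform(c.release_box[0], c.release_box[1])),
            float(rng.uniform(c.release_box[2], c.release_box[3])),
        )
        start = start_lo + int(rng.integers(span))
        child_seed = int(rng.integers(2**31 - 1))
        fish = simulate_individual(
            sp, T, child_seed, start_date=start, origin=origin, fish_id=fid
        )
        fish.rich = rich
        if include_depth:
            fish.depth = simulate_depth(fish, child_seed + 1)
        fishes.append(fish)
    return fishes


def write_cohort(fishes: list[SimulatedFish], outdir) -> dict[str, str]:
    """Write a cohort in the raw input CSV formats plus truth files.

    Emits tracks.csv, metadata.csv, truth_states.csv, truth_params.csv and,
    for fish carrying a simulated depth series, depth.csv. Returns the file
    paths written.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    rows = []
    for f in fishes:
        rows.append(
            pd.DataFrame(
                {
                    "fish_id": f.track.fish_id,
                    "date": f.track.dates.astype(str),
                    "lat": f.track.lat,
                    "lon": f.track.lon,
                }
            )
        )
    paths["tracks"] = os.path.join(outdir, "tracks.csv")
    pd.concat(rows, ignore_index=True).to_csv(paths["tracks"], index=False, float_format="%.8f")

    meta = pd.DataFrame(
        [
            {
                "fish_id": f.metadata.fish_id,
                "species": f.metadata.species,
                "substock": f.metadata.substock,
                "release_date": str(f.metadata.release_date),
                "end_date": str(f.metadata.end_date),
            }
            for f in fishes
        ]
    )
    paths["metadata"] = os.path.join(outdir, "metadata.csv")
    meta.to_csv(paths["metadata"], index=False)

    truth = pd.concat(
        [
            pd.DataFrame(
                {
                    "fish_id": f.path.fish_id,
                    "date": f.path.dates.astype(str),
                    "true_state": np.asarray(["R", "M"])[f.states],
                }
            )
            for f in fishes
        ],
        ignore_index=True,
    )
    paths["truth_states"] = os.path.join(outdir, "truth_states.csv")
    truth.to_csv(paths["truth_states"], index=False)

    prows = []
    for f in fishes:
        p = f.params
        prows.append(
            {
                "fish_id": f.path.fish_id,
                "gamma_rr": p.gamma_rr,
                "gamma_mm": p.gamma_mm,
                "mu_rh": p.mu[0, 0],
                "mu_rv": p.mu[0, 1],
                "mu_mh": p.mu[1, 0],
                "mu_mv": p.mu[1, 1],
                "sigma_rh": p.sigma[0, 0],
                "sigma_rv": p.sigma[0, 1],
                "sigma_mh": p.sigma[1, 0],
                "sigma_mv": p.sigma[1, 1],
                "rho_r": p.rho[0],
                "rho_m": p.rho[1],
            }
        )
    paths["truth_params"] = os.path.join(outdir, "truth_params.csv")
    pd.DataFrame(prows).to_csv(paths["truth_params"], index=False, float_format="%.8f")

    with_depth = [f for f in fishes if f.depth is not None]
    if with_depth:
        drows = [
            pd.DataFrame(
                {
                    "fish_id": f.depth.fish_id,
                    "timestamp": f.depth.timestamps.astype(str),
                    "depth_m": f.depth.depths,
                }
            )
            for f in with_depth
        ]
        paths["depth"] = os.path.join(outdir, "depth.csv")
        pd.concat(drows, ignore_index=True).to_csv(paths["depth"], index=False, float_format="%.4f")
    return paths
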