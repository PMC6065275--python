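"""Population-level summaries of decoded individual behaviour.

Scales per-fish state sequences up to the population: weekly state
probabilities and proportions across the calendar year, state-dominant
seasonal windows (weekly mean probability > 0.5, consecutive weeks grouped,
wrapping across new year), state-conditional space use on a 5 km x 5 km grid,
state-dependent movement rates by substock, and a geometric check on state
dwell times (first-order Markov switching implies geometrically distributed
run lengths).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hmm import MIGRATING, RESIDENT, FittedModel
from .io import UsageError
from .preprocess import EARTH_RADIUS_M

N_WEEKS = 52


def week_of_year(dates: np.ndarray) -> np.ndarray:
    """Week number 1..52: week w covers days 7(w-1)+1 .. 7w from 1 January.

    Days 365/366 fold into week 52. Independent of year.
    """
    doy = pd.DatetimeIndex(np.asarray(dates, dtype="datetime64[D]")).dayofyear.to_numpy()
    return np.minimum((doy - 1) // 7 + 1, N_WEEKS)


# ---------------------------------------------------------------------------
# Weekly state summaries
# ---------------------------------------------------------------------------


def weekly_state_summary(fits: list[FittedModel]) -> pd.DataFrame:
    """Weekly population summary of the resident state.

    Per calendar week (pooling years): ``mean_p_resident`` is the mean of the
    smoothed resident probability over all fish-days; ``se`` the standard
    error across per-fish weekly means; ``prop_resident`` the fraction of
    fish-days allocated to R; ``n_fish`` the number of fish at liberty that
    week. Weeks with no fish are emitted with n_fish = 0 and NaN summaries.
    """
    recs = []
    for f in fits:
        if f.smoothed is None:
            raise UsageError(f"{f.path.fish_id}: fit not decoded")
        recs.append(
            pd.DataFrame(
                {
                    "fish_id": f.path.fish_id,
                    "week": week_of_year(f.path.dates),
                    "p_res": f.smoothed[:, RESIDENT],
                    "is_res": f.states == RESIDENT,
                }
            )
        )
    df = pd.concat(recs, ignore_index=True)
    out = []
    for w in range(1, N_WEEKS + 1):
        sub = df[df["week"] == w]
        n_fish = sub["fish_id"].nunique()
        if n_fish == 0:
            out.append((w, np.nan, np.nan, np.nan, 0))
            continue
        per_fish = sub.groupby("fish_id")["p_res"].mean()
        se = float(per_fish.std(ddof=1) / math.sqrt(n_fish)) if n_fish > 1 else 0.0
        out.append(
            (w, float(sub["p_res"].mean()), se, float(sub["is_res"].mean()), n_fish)
        )
    return pd.DataFrame(
        out, columns=["week", "mean_p_resident", "se", "prop_resident", "n_fish"]
    )


def state_dominant_windows(
    summary: pd.DataFrame, state: int = RESIDENT, threshold: float = 0.5
) -> list[tuple[int, int]]:
    """Maximal runs of weeks whose mean state probability exceeds threshold.

    Runs are circular: a window may wrap week 52 -> week 1 (winter-spanning
    migration seasons). Strict inequality, so a flat 0.5 yields no windows.
    Returns (start_week, end_week) pairs inclusive; end < start marks a wrap.
    """
    s = summary.sort_values("week")
    p = s["mean_p_resident"].to_numpy()
    if state == MIGRATING:
        p = 1.0 - p
    hot = p > threshold
    hot = np.where(np.isnan(p), False, hot)
    if hot.all():
        return [(1, N_WEEKS)]
    if not hot.any():
        return []
    # rotate so the scan starts on a cold week, then collect linear runs
    start0 = int(np.flatnonzero(~hot)[0])
    windows = []
    run_start = None
    for k in range(N_WEEKS + 1):
        idx = (start0 + k) % N_WEEKS
        if k < N_WEEKS and hot[idx]:
            if run_start is None:
                run_start = idx
        elif run_start is not None:
            end = (start0 + k - 1) % N_WEEKS
            windows.append((run_start + 1, end + 1))
            run_start = None
    return sorted(windows)


def weeks_in_window(window: tuple[int, int]) -> set[int]:
    """Expand an inclusive (start, end) week range, wrapping 52 -> 1."""
    start, end = window
    if start <= end:
        return set(range(start, end + 1))
    return set(range(start, N_WEEKS + 1)) | set(range(1, end + 1))


# ---------------------------------------------------------------------------
# Utilization grids
# ---------------------------------------------------------------------------


def _laea_forward(lat, lon, lat0, lon0):
    """Lambert azimuthal equal-area projection (m) about (lat0, lon0)."""
    phi, lam = np.radians(lat), np.radians(lon)
    phi0, lam0 = math.radians(lat0), math.radians(lon0)
    c = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    k = np.sqrt(2.0 / np.maximum(c, 1e-12))
    x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_M * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def _laea_inverse(x, y, lat0, lon0):
    phi0, lam0 = math.radians(lat0), math.radians(lon0)
    x = np.asarray(x, float) / EARTH_RADIUS_M
    y = np.asarray(y, float) / EARTH_RADIUS_M
    rho = np.sqrt(x * x + y * y)
    c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
    with np.errstate(invalid="ignore"):
        phi = np.where(
            rho == 0,
            phi0,
            np.arcsin(np.cos(c) * math.sin(phi0) + y * np.sin(c) * math.cos(phi0) / np.where(rho == 0, 1, rho)),
        )
        lam = lam0 + np.arctan2(
            x * np.sin(c),
            rho * math.cos(phi0) * np.cos(c) - y * math.sin(phi0) * np.sin(c),
        )
    return np.degrees(phi), np.degrees(lam)


@dataclass
class UtilizationGrid:
    """Fish-day counts of one state over a square lattice (equal-area plane)."""

    state: int
    window: tuple[int, int]
    cell_km: float
    lat0: float
    lon0: float
    cells: pd.DataFrame  # cell_x, cell_y, lon_center, lat_center, count

    @property
    def total(self) -> int:
        return int(self.cells["count"].sum()) if len(self.cells) else 0

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False, float_format="%.6f")


def utilization_grid(
    fits: list[FittedModel],
    window: tuple[int, int],
    state: int = RESIDENT,
    cell_km: float = 5.0,
) -> UtilizationGrid:
    """Bin state-classified fish-days into cell_km x cell_km grid cells.

    A fish-day contributes when its calendar week falls inside ``window`` and
    its allocated state equals ``state``. Positions are projected with a local
    azimuthal equal-area projection centred on the contributing-day centroid,
    keeping cell areas honest at North-Sea scale; the grid is unbounded (any
    position simply maps to its containing cell).
    """
    wk = weeks_in_window(window)
    lats, lons = [], []
    for f in fits:
        weeks = week_of_year(f.path.dates)
        m = (f.states == state) & np.isin(weeks, list(wk))
        lats.append(f.path.lat[m])
        lons.append(f.path.lon[m])
    lat = np.concatenate(lats) if lats else np.empty(0)
    lon = np.concatenate(lons) if lons else np.empty(0)
    if lat.size == 0:
        cells = pd.DataFrame(columns=["cell_x", "cell_y", "lon_center", "lat_center", "count"])
        return UtilizationGrid(state, window, cell_km, 0.0, 0.0, cells)
    lat0, lon0 = float(lat.mean()), float(lon.mean())
    x, y = _laea_forward(lat, lon, lat0, lon0)
    size = cell_km * 1000.0
    ix = np.floor(x / size).astype(int)
    iy = np.floor(y / size).astype(int)
    counts = pd.DataFrame({"cell_x": ix, "cell_y": iy}).value_counts().reset_index(name="count")
    cx = (counts["cell_x"].to_numpy() + 0.5) * size
    cy = (counts["cell_y"].to_numpy() + 0.5) * size
    clat, clon = _laea_inverse(cx, cy, lat0, lon0)
    counts["lon_center"] = clon
    counts["lat_center"] = clat
    counts = counts[["cell_x", "cell_y", "lon_center", "lat_center", "count"]]
    counts = counts.sort_values(["cell_x", "cell_y"]).reset_index(drop=True)
    return UtilizationGrid(state, window, cell_km, lat0, lon0, counts)


# ---------------------------------------------------------------------------
# Substock movement rates
# ---------------------------------------------------------------------------


def substock_rates(fits: list[FittedModel]) -> pd.DataFrame:
    """State-dependent mean movement rates by species x substock.

    Per fish and state: the arithmetic mean of the raw daily rates (exp of the
    log metrics) over the days allocated to that state; then the unweighted
    mean across the substock's fish. Horizontal in km/day, vertical in m/day.
    A fish with no days in a state contributes nothing to that cell.
    """
    rows = []
    for f in fits:
        p = f.path
        for j, sname in ((RESIDENT, "resident"), (MIGRATING, "migrating")):
            m = f.states == j
            if not m.any():
                continue
            rows.append(
                {
                    "species": p.species,
                    "substock": p.substock,
                    "state": sname,
                    "fish_id": p.fish_id,
                    "h_km_day": float(np.exp(p.h[m]).mean()) / 1000.0,
                    "v_m_day": float(np.exp(p.v[m]).mean()),
                }
            )
    per_fish = pd.DataFrame(rows)
    if per_fish.empty:
        return per_fish
    out = (
        per_fish.groupby(["species", "substock", "state"])
        .agg(
            horizontal_km_day=("h_km_day", "mean"),
            vertical_m_day=("v_m_day", "mean"),
            n_fish=("fish_id", "nunique"),
        )
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# Dwell times
# ---------------------------------------------------------------------------


@dataclass
class DwellTimeTable:
    """Pooled per-state run lengths with censoring flags and geometric fit.

    Runs touching either end of a fish's series are censored (their true
    length is unknown) and excluded from the geometric fit. The geometric MLE
    on support {1, 2, ...} is p_hat = 1 / mean(uncensored runs).
    """

    runs: dict[int, np.ndarray]
    censored: dict[int, np.ndarray]
    p_hat: dict[int, float] = field(default_factory=dict)
    chi2: dict[int, float] = field(default_factory=dict)
    pvalue: dict[int, float] = field(default_factory=dict)
    pooled_mean: float = float("nan")
    pooled_pvalue: float = float("nan")
    pooled_n: int = 0
    degenerate: bool = False


def extract_runs(states: np.ndarray) -> list[tuple[int, int, bool]]:
    """(state, length, censored) runs of a decoded sequence, in order."""
    states = np.asarray(states)
    if states.size == 0:
        return []
    change = np.flatnonzero(np.diff(states) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [states.size - 1]])
    out = []
    for s, e in zip(starts, ends):
        censored = s == 0 or e == states.size - 1
        out.append((int(states[s]), int(e - s + 1), censored))
    return out


def _geometric_gof(lengths: np.ndarray) -> tuple[float, float, float]:
    """Chi-square GOF of run lengths against Geometric(p_hat); returns
    (p_hat, statistic, pvalue)."""
    n = lengths.size
    mean = lengths.mean()
    p = 1.0 / mean
    # bins 1..k plus a tail, merged so every expected count >= 5
    kmax = int(lengths.max())
    pmf = p * (1 - p) ** (np.arange(1, kmax + 1) - 1)
    tail = (1 - p) ** kmax
    probs = np.append(pmf, tail)
    obs = np.append(np.bincount(lengths, minlength=kmax + 1)[1:], 0)
    # merge from the right until expected >= 5 per bin
    merged_obs, merged_p = [], []
    acc_o, acc_p = 0.0, 0.0
    for o, q in zip(obs, probs):
        acc_o += o
        acc_p += q
        if acc_p * n >= 5.0:
            merged_obs.append(acc_o)
            merged_p.append(acc_p)
            acc_o, acc_p = 0.0, 0.0
    if acc_p > 0 and merged_obs:
        merged_obs[-1] += acc_o
        merged_p[-1] += acc_p
    if len(merged_obs) < 3:
        return p, float("nan"), float("nan")
    exp = np.array(merged_p) * n
    statistic = float(np.sum((np.array(merged_obs) - exp) ** 2 / exp))
    dof = len(merged_obs) - 1 - 1  # one estimated parameter
    return p, statistic, float(stats.chi2.sf(statistic, dof))


def dwell_time_analysis(fits: list[FittedModel]) -> DwellTimeTable:
    """Pool decoded run lengths across fish and test them against geometry."""
    runs: dict[int, list[int]] = {RESIDENT: [], MIGRATING: []}
    cens: dict[int, list[int]] = {RESIDENT: [], MIGRATING: []}
    for f in fits:
        if f.states is None:
            raise UsageError(f"{f.path.fish_id}: fit not decoded")
        for j, length, censored in extract_runs(f.states):
            (cens if censored else runs)[j].append(length)
    table = DwellTimeTable(
        runs={j: np.array(v, dtype=int) for j, v in runs.items()},
        censored={j: np.array(v, dtype=int) for j, v in cens.items()},
    )
    pooled = np.concatenate([table.runs[RESIDENT], table.runs[MIGRATING]])
    if pooled.size == 0:
        table.degenerate = True
        return table
    for j in (RESIDENT, MIGRATING):
        if table.runs[j].size >= 2:
            p, chi2, pv = _geometric_gof(table.runs[j])
            table.p_hat[j], table.chi2[j], table.pvalue[j] = p, chi2, pv
    table.pooled_mean = float(pooled.mean())
    table.pooled_n = int(pooled.size)
    _, _, table.pooled_pvalue = _geometric_gof(pooled)
    return table
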