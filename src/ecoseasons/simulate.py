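"""Regime-switching telemetry and weather simulation with known ground truth.

The walker is a biased correlated random walk: within each behavioral regime
(the simulated analog of a seasonal space-use state) step lengths follow a
gamma law, turning angles a von Mises law, and habitat preference enters
through a discrete-choice approximation — at every step K candidate
endpoints are drawn from the step/turn law and one is kept with probability
proportional to ``exp(habitat_weights . covariates)`` at the endpoint,
optionally shaded by a Gaussian home-range attraction around the
individual's start point (range residency).
Regime day-windows are shared across all individuals of a population, so the
population has a single true :class:`~ecoseasons.season_calendar.SeasonCalendar`
that downstream clustering should recover.

Simulated fixes are emitted on a regular schedule with uniform +/-15 min
timestamp jitter and independent random fix failures, emulating the
irregular intervals a resampler has to handle.  Timestamps start on
2001-01-01 (UTC); leap days are skipped so every simulated year has exactly
365 days.

Weather is a sinusoidal annual temperature cycle with Gaussian noise; snow
depth is positive only while the smoothed temperature is below freezing, so
green-up (daily growing-degree-day change) and snow depth are negatively
associated by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, StuckWalkerError
from .landscape import CONTINUOUS_LAYERS, LandscapeStack
from .season_calendar import DAYS_PER_YEAR, SeasonCalendar, SeasonState, circular_day

TRACK_COLUMNS = ["individual_id", "timestamp", "x", "y"]
SIM_EPOCH = pd.Timestamp("2001-01-01 00:00:00", tz="UTC")


@dataclass
class RegimeSpec:
    """One behavioral regime (ground-truth season) of the walk.

    ``step_scale`` is the gamma scale parameter theta in meters and
    ``step_shape`` the gamma shape k, so the mean step length is
    ``step_shape * step_scale``.  ``habitat_weights`` maps land-cover class
    names and continuous layer names (slope, northness, dist_lake,
    dist_road) to selection strengths on the log scale, per unit of the raw
    layer value; missing entries mean no preference.
    """

    name: str
    start_day: int
    end_day: int
    step_scale: float = 100.0
    step_shape: float = 2.0
    angular_concentration: float = 0.5
    habitat_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.step_scale <= 0:
            raise InvalidConfigError(f"step_scale must be > 0, got {self.step_scale}")
        if self.step_shape <= 0:
            raise InvalidConfigError(f"step_shape must be > 0, got {self.step_shape}")
        if self.angular_concentration < 0:
            raise InvalidConfigError("angular_concentration must be >= 0")


@dataclass
class SimConfig:
    """Population-level simulation settings.

    ``home_range_sd`` adds central-place attraction: candidate endpoints
    are additionally weighted by a Gaussian of that SD (meters) around the
    individual's start point, making each walker a range resident, as
    collared wolves, moose and deer are.  Set it to None for an unbounded
    walk (useful for availability-matching checks).
    """

    regimes: list[RegimeSpec]
    n_individuals: int = 12
    fix_interval_hours: float = 4.0
    fix_jitter_minutes: float = 15.0
    fix_failure_prob: float = 0.05
    n_years: int = 2
    n_candidates: int = 30
    home_range_sd: float | None = 1000.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise InvalidConfigError("n_individuals must be >= 1")
        if self.fix_interval_hours <= 0:
            raise InvalidConfigError("fix_interval_hours must be > 0")
        if not 0 <= self.fix_failure_prob < 1:
            raise InvalidConfigError("fix_failure_prob must be in [0, 1)")
        _validate_regime_windows(self.regimes)

    def true_calendar(self) -> SeasonCalendar:
        """The shared ground-truth season calendar of the population."""
        states = [
            SeasonState(r.name, r.start_day, r.end_day)
            for r in _chronological(self.regimes)
        ]
        return SeasonCalendar(states=states, provenance={"source": "simulation"})


def _chronological(regimes: list[RegimeSpec]) -> list[RegimeSpec]:
    return sorted(regimes, key=lambda r: r.start_day)


def _validate_regime_windows(regimes: list[RegimeSpec]):
    if not regimes:
        raise InvalidConfigError("at least one regime required")
    if len(regimes) == 1:
        r = regimes[0]
        if (r.end_day - r.start_day) % DAYS_PER_YEAR != DAYS_PER_YEAR - 1:
            raise InvalidConfigError("a single regime must span the full year")
        return
    ordered = _chronological(regimes)
    covered = 0
    for prev, cur in zip(ordered, ordered[1:] + ordered[:1]):
        if circular_day(prev.end_day + 1) != cur.start_day:
            raise InvalidConfigError(
                f"regime windows must tile the year: {prev.name!r} ends day "
                f"{prev.end_day} but {cur.name!r} starts day {cur.start_day}"
            )
        covered += (prev.end_day - prev.start_day) % DAYS_PER_YEAR + 1
    if covered != DAYS_PER_YEAR:
        raise InvalidConfigError("regime windows overlap or leave gaps")


def individual_seed(rng_seed: int, index: int) -> int:
    """Deterministic per-individual seed derived from the population seed."""
    return int(np.random.SeedSequence([rng_seed, index]).generate_state(1)[0] % 2**31)


def _sim_times(n_years: int, fix_interval_hours: float) -> pd.DatetimeIndex:
    """Fix-schedule timestamps over n_years of 365 days, leap days skipped."""
    hours = np.arange(0, n_years * DAYS_PER_YEAR * 24, fix_interval_hours)
    times = SIM_EPOCH + pd.to_timedelta(hours, unit="h")
    # SIM_EPOCH year 2001 is non-leap; later leap days are skipped by
    # mapping elapsed days directly to a 365-day ordinal year below, so the
    # wall-clock dates here are only a monotone time axis.
    return pd.DatetimeIndex(times)


def _ordinal_days(times: pd.DatetimeIndex) -> np.ndarray:
    """Ordinal day 1..365 from elapsed days since the simulation epoch."""
    elapsed = (times - SIM_EPOCH) / pd.Timedelta(days=1)
    return (np.floor(elapsed).astype(int) % DAYS_PER_YEAR) + 1


def _regime_score_grid(landscape: LandscapeStack, regime: RegimeSpec) -> np.ndarray:
    score = np.zeros_like(landscape.slope, dtype=float)
    for key, w in regime.habitat_weights.items():
        if w == 0:
            continue
        if key in landscape.classes:
            score += w * (landscape.land_cover == landscape.classes.index(key))
        elif key in CONTINUOUS_LAYERS:
            score += w * getattr(landscape, key)
        else:
            raise InvalidConfigError(f"unknown habitat_weights key {key!r}")
    return score


def _regime_index_by_day(regimes: list[RegimeSpec]) -> np.ndarray:
    idx = np.full(DAYS_PER_YEAR + 1, -1, dtype=int)
    for i, r in enumerate(regimes):
        d = r.start_day
        for _ in range(1, (r.end_day - r.start_day) % DAYS_PER_YEAR + 2):
            idx[d] = i
            d = circular_day(d + 1)
    return idx


def simulate_track(
    landscape: LandscapeStack,
    regimes: list[RegimeSpec],
    sim_config: SimConfig,
    individual_id: str,
    seed: int,
) -> pd.DataFrame:
    """Simulate one individual's track.

    Returns a Movebank-style frame with columns individual_id, timestamp
    (UTC), x, y and true_regime (the ground-truth regime name per fix, which
    the analysis pipeline never sees).
    """
    _validate_regime_windows(regimes)
    rng = np.random.default_rng(seed)
    grid = landscape.grid
    xmin, xmax, ymin, ymax = grid.extent
    score_grids = [_regime_score_grid(landscape, r) for r in regimes]
    regime_of_day = _regime_index_by_day(regimes)

    times = _sim_times(sim_config.n_years, sim_config.fix_interval_hours)
    days = _ordinal_days(times)
    n_steps = len(times)
    K = sim_config.n_candidates

    # start at a uniform interior point; the start doubles as the
    # home-range center when central-place attraction is on
    pad = 2 * grid.cell_size
    x = rng.uniform(xmin + pad, xmax - pad)
    y = rng.uniform(ymin + pad, ymax - pad)
    heading = rng.uniform(-np.pi, np.pi)
    home_sd = sim_config.home_range_sd
    home_x, home_y = x, y

    xs = np.empty(n_steps)
    ys = np.empty(n_steps)
    regime_names = np.empty(n_steps, dtype=object)
    xs[0], ys[0] = x, y
    regime_names[0] = regimes[regime_of_day[days[0]]].name

    for i in range(1, n_steps):
        ri = regime_of_day[days[i]]
        reg = regimes[ri]
        score = score_grids[ri]
        for attempt in range(10):
            if reg.angular_concentration > 0:
                turns = rng.vonmises(0.0, reg.angular_concentration, size=K)
            else:
                turns = rng.uniform(-np.pi, np.pi, size=K)
            lengths = rng.gamma(reg.step_shape, reg.step_scale, size=K)
            heads = heading + turns
            cx = x + lengths * np.cos(heads)
            cy = y + lengths * np.sin(heads)
            ok = (cx >= xmin) & (cx < xmax) & (cy > ymin) & (cy <= ymax)
            if ok.any():
                break
        else:
            raise StuckWalkerError(
                f"individual {individual_id}: no on-landscape candidate after "
                f"10 redraws at step {i}",
                position=(x, y),
            )
        idx = np.flatnonzero(ok)
        row, col = grid.rowcol(cx[idx], cy[idx])
        s = score[row, col]
        if home_sd is not None:
            d2 = (cx[idx] - home_x) ** 2 + (cy[idx] - home_y) ** 2
            s = s - d2 / (2.0 * home_sd**2)
        s = s - s.max()
        p = np.exp(s)
        p /= p.sum()
        choice = idx[rng.choice(len(idx), p=p)]
        x, y = cx[choice], cy[choice]
        heading = heads[choice]
        xs[i], ys[i] = x, y
        regime_names[i] = reg.name

    # emit fixes: independent failures, uniform timestamp jitter
    kept = rng.uniform(size=n_steps) >= sim_config.fix_failure_prob
    jitter_min = rng.uniform(
        -sim_config.fix_jitter_minutes, sim_config.fix_jitter_minutes, size=n_steps
    )
    stamps = times + pd.to_timedelta(jitter_min, unit="min")
    track = pd.DataFrame(
        {
            "individual_id": individual_id,
            "timestamp": stamps[kept],
            "x": xs[kept],
            "y": ys[kept],
            "true_regime": regime_names[kept],
        }
    ).reset_index(drop=True)
    return track


def simulate_population(
    landscape: LandscapeStack, sim_config: SimConfig
) -> tuple[list[pd.DataFrame], SeasonCalendar]:
    """Simulate all individuals of a population.

    Individuals are independent walks sharing the regime day-windows; the
    returned calendar is the shared ground truth.  Fully deterministic given
    ``sim_config.rng_seed``.
    """
    tracks = []
    for i in range(sim_config.n_individuals):
        tracks.append(
            simulate_track(
                landscape,
                sim_config.regimes,
                sim_config,
                individual_id=f"ind_{i:02d}",
                seed=individual_seed(sim_config.rng_seed, i),
            )
        )
    return tracks, sim_config.true_calendar()


def simulate_weather(
    n_years: int,
    seed: int,
    winter_min_c: float = -17.8,
    summer_max_c: float = 23.3,
    noise_sd: float = 3.0,
    snow_per_degree_cm: float = 2.5,
    smooth_days: int = 15,
) -> pd.DataFrame:
    """Daily weather table: date, mean_temp (C), snow_depth (cm).

    The annual cycle is a cosine with its minimum on ordinal day 15
    (mid-January) and maximum half a year later, matching the configured
    extremes exactly when ``noise_sd`` is 0.  Snow depth is proportional to
    the magnitude of the smoothed sub-freezing temperature (with
    multiplicative noise) and exactly zero when the smoothed temperature is
    at or above 0 C.
    """
    if n_years < 1:
        raise InvalidConfigError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    n_days = n_years * DAYS_PER_YEAR
    doy = np.arange(n_days) % DAYS_PER_YEAR + 1
    mid = (summer_max_c + winter_min_c) / 2
    amp = (summer_max_c - winter_min_c) / 2
    temp = mid - amp * np.cos(2 * np.pi * (doy - 15) / DAYS_PER_YEAR)
    temp = temp + rng.normal(0.0, noise_sd, size=n_days)

    smoothed = (
        pd.Series(temp)
        .rolling(smooth_days, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    snow = np.where(smoothed < 0, snow_per_degree_cm * (-smoothed), 0.0)
    snow = snow * np.exp(rng.normal(0.0, 0.2, size=n_days) * (noise_sd > 0))
    snow = np.maximum(snow, 0.0)

    dates = SIM_EPOCH + pd.to_timedelta(np.arange(n_days), unit="D")
    return pd.DataFrame(
        {"date": dates.normalize(), "mean_temp": temp, "snow_depth": snow}
    )


def write_tracks(tracks: list[pd.DataFrame], path) -> None:
    """Write tracks as a single Movebank-style CSV (ISO-8601 UTC stamps)."""
    df = pd.concat(tracks, ignore_index=True)
    df = df.copy()
    df["timestamp"] = df["timestamp"].dt.round("us").dt.strftime(
        "%Y-%m-%dT%H:%M:%S.%f%z"
    )
    df.to_csv(path, index=False)


def read_tracks(path) -> list[pd.DataFrame]:
    """Read a Movebank-style CSV back into one frame per individual."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return [g.reset_index(drop=True) for _, g in df.groupby("individual_id", sort=True)]
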