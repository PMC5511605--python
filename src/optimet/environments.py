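"""Candidate field environments: sites, weather series and day length.

A candidate environment is a (site, sowing date) pair together with the
daily mean-temperature and day-length series the crop model needs.  When a
trial network is being planned, next season's temperatures are unknown, so
designs are scored on a virtual "average year" — the per-calendar-day mean
of several past years — while day length is known exactly from latitude.

Because the historical weather records behind a real study are rarely
shareable, the module also ships a seasonal-sinusoid + AR(1) synthetic
weather generator that reproduces the features the design criterion is
sensitive to: a latitude-dependent mean, a seasonal cycle, and day-to-day
autocorrelated noise.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Site",
    "WeatherSeries",
    "Environment",
    "ClimateParams",
    "day_length",
    "average_year",
    "generate_synthetic_weather",
    "concat_years",
    "extend_cyclic",
    "build_environments",
]

TMEAN_MIN, TMEAN_MAX = -40.0, 55.0


@dataclasses.dataclass(frozen=True)
class Site:
    """A candidate trial location identified by its latitude."""

    site_id: str
    name: str
    latitude_deg: float

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be a non-empty string")
        if not math.isfinite(self.latitude_deg) or abs(self.latitude_deg) > 90:
            raise ValueError(f"latitude must be finite and within [-90, 90], got {self.latitude_deg}")


@dataclasses.dataclass
class WeatherSeries:
    """Daily mean air temperatures (°C) for one site over consecutive dates."""

    site_id: str
    dates: pd.DatetimeIndex
    tmean_c: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmean_c = np.asarray(self.tmean_c, dtype=float)
        if len(self.dates) != len(self.tmean_c):
            raise ValueError("dates and tmean_c must have equal length")
        if len(self.dates) > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
            if np.any(deltas <= 0):
                raise ValueError("dates must be strictly increasing")
        bad = ~((self.tmean_c >= TMEAN_MIN) & (self.tmean_c <= TMEAN_MAX))
        if np.any(bad):
            raise ValueError(
                f"temperatures outside [{TMEAN_MIN}, {TMEAN_MAX}] °C at "
                f"{self.dates[np.flatnonzero(bad)[0]].date()}"
            )

    def __len__(self) -> int:
        return len(self.dates)


@dataclasses.dataclass
class Environment:
    """One candidate trial: a site sown on a given date, with its covariates.

    ``tmean_c`` and ``daylength_h`` are indexed by days after sowing
    (0-based; day 0 is the sowing day) and have length ``horizon_days``.
    """

    env_id: str
    site: Site
    sowing_date: dt.date
    tmean_c: np.ndarray
    daylength_h: np.ndarray

    def __post_init__(self) -> None:
        self.tmean_c = np.asarray(self.tmean_c, dtype=float)
        self.daylength_h = np.asarray(self.daylength_h, dtype=float)
        if len(self.tmean_c) != len(self.daylength_h):
            raise ValueError("tmean_c and daylength_h must have equal length")
        if self.horizon_days < 250:
            raise ValueError(f"horizon_days must be >= 250, got {self.horizon_days}")
        if np.any((self.daylength_h < 0) | (self.daylength_h > 24)):
            raise ValueError("day lengths must lie in [0, 24] h")

    @property
    def horizon_days(self) -> int:
        return len(self.tmean_c)


def day_length(latitude_deg: float, day_of_year: int) -> float:
    """Astronomical day length (sunrise to sunset) in hours.

    Uses the standard agronomic formula: solar declination
    delta = 23.45° · sin(2π (284 + doy) / 365) and half-day angle
    arccos(−tan(phi) tan(delta)), with the arccos argument clamped to
    [−1, 1] so polar day / polar night return 24 h / 0 h.
    """
    lat = float(latitude_deg)
    if not math.isfinite(lat) or abs(lat) > 90:
        raise ValueError(f"latitude must lie in [-90, 90], got {latitude_deg}")
    doy = int(day_of_year)
    if not 1 <= doy <= 366:
        raise ValueError(f"day_of_year must lie in 1..366, got {day_of_year}")
    decl = math.radians(23.45) * math.sin(2.0 * math.pi * (284 + doy) / 365.0)
    arg = -math.tan(math.radians(lat)) * math.tan(decl)
    arg = min(1.0, max(-1.0, arg))
    return 24.0 / math.pi * math.acos(arg)


def _day_length_vector(latitude_deg: float, days_of_year: np.ndarray) -> np.ndarray:
    decl = np.radians(23.45) * np.sin(2.0 * np.pi * (284 + days_of_year) / 365.0)
    arg = np.clip(-np.tan(np.radians(latitude_deg)) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(arg)


def average_year(series_by_year: Sequence[WeatherSeries]) -> WeatherSeries:
    """Average several years of one site's weather into a virtual year.

    The value on calendar day (month, day) is the mean of that day across
    years; Feb 29 is dropped before averaging.  All years must cover the
    same (month, day) window, otherwise an error lists the missing days.
    The returned series reuses the calendar of the first input year.
    """
    series = list(series_by_year)
    if len(series) < 2:
        raise ValueError("average_year needs at least 2 input years")
    site_ids = {s.site_id for s in series}
    if len(site_ids) > 1:
        raise ValueError(f"all series must belong to one site, got {sorted(site_ids)}")

    frames = []
    for idx, s in enumerate(series):
        keep = ~((s.dates.month == 2) & (s.dates.day == 29))
        frames.append(
            pd.DataFrame(
                {
                    "md": list(zip(s.dates.month[keep], s.dates.day[keep])),
                    "tmean": s.tmean_c[keep],
                    "year_idx": idx,
                }
            )
        )
    table = pd.concat(frames)
    counts = table.groupby("md")["year_idx"].nunique()
    missing = counts[counts < len(series)]
    if len(missing) > 0:
        days = ", ".join(f"{m:02d}-{d:02d}" for m, d in missing.index[:10])
        raise ValueError(f"years have mismatched day coverage; incomplete days: {days}")
    means = table.groupby("md")["tmean"].mean()

    first = series[0]
    keep = ~((first.dates.month == 2) & (first.dates.day == 29))
    dates = first.dates[keep]
    values = means.loc[list(zip(dates.month, dates.day))].to_numpy()
    return WeatherSeries(first.site_id, dates, values)


@dataclasses.dataclass(frozen=True)
class ClimateParams:
    """Seasonal-sinusoid climate for the synthetic weather generator.

    Annual mean = ``mean_at_45`` + ``mean_lat_slope`` · (latitude − 45),
    seasonal amplitude ``amplitude_c`` with the coldest day at
    ``coldest_doy``, plus AR(1) noise with stationary sd ``noise_sd`` and
    lag-1 autocorrelation ``rho``.  Defaults are plausible temperate
    values; only the contrast between environments matters for design.
    """

    mean_at_45: float = 13.5
    mean_lat_slope: float = -0.25
    amplitude_c: float = 8.0
    coldest_doy: int = 20
    noise_sd: float = 2.5
    rho: float = 0.7


def generate_synthetic_weather(
    sites: Sequence[Site],
    n_years: int,
    climate: ClimateParams | None = None,
    seed: int | None = 0,
    start_year: int = 2001,
) -> list[WeatherSeries]:
    """Generate one full calendar year of daily temperatures per site/year.

    Returns one :class:`WeatherSeries` per site per year (``n_years``
    consecutive years starting at ``start_year``); the AR(1) noise is
    continuous across year boundaries within a site.  Reproducible under
    ``seed``.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    climate = climate or ClimateParams()
    if climate.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not -1 < climate.rho < 1:
        raise ValueError("rho must lie in (-1, 1)")
    rng = np.random.default_rng(seed)

    out: list[WeatherSeries] = []
    dates_all = pd.date_range(
        dt.date(start_year, 1, 1), dt.date(start_year + n_years - 1, 12, 31), freq="D"
    )
    doy = dates_all.dayofyear.to_numpy()
    for site in sites:
        mean = climate.mean_at_45 + climate.mean_lat_slope * (site.latitude_deg - 45.0)
        seasonal = mean - climate.amplitude_c * np.cos(
            2.0 * np.pi * (doy - climate.coldest_doy) / 365.25
        )
        if climate.noise_sd > 0:
            innov_sd = climate.noise_sd * math.sqrt(1.0 - climate.rho**2)
            eps = np.empty(len(dates_all))
            eps[0] = rng.normal(0.0, climate.noise_sd)
            innov = rng.normal(0.0, innov_sd, size=len(dates_all) - 1)
            for t in range(1, len(dates_all)):
                eps[t] = climate.rho * eps[t - 1] + innov[t - 1]
        else:
            eps = np.zeros(len(dates_all))
        temps = np.clip(seasonal + eps, TMEAN_MIN, TMEAN_MAX)
        for y in range(n_years):
            mask = dates_all.year == start_year + y
            out.append(WeatherSeries(site.site_id, dates_all[mask], temps[mask]))
    return out


def concat_years(series_by_year: Sequence[WeatherSeries]) -> WeatherSeries:
    """Concatenate consecutive per-year series of one site into one series."""
    series = sorted(series_by_year, key=lambda s: s.dates[0])
    if not series:
        raise ValueError("no series to concatenate")
    dates = series[0].dates
    values = [series[0].tmean_c]
    for s in series[1:]:
        if s.site_id != series[0].site_id:
            raise ValueError("series belong to different sites")
        if (s.dates[0] - dates[-1]).days != 1:
            raise ValueError(f"gap between {dates[-1].date()} and {s.dates[0].date()}")
        dates = dates.append(s.dates)
        values.append(s.tmean_c)
    return WeatherSeries(series[0].site_id, dates, np.concatenate(values))


def extend_cyclic(series: WeatherSeries, n_days: int) -> WeatherSeries:
    """Extend a virtual-year series periodically by ``n_days``.

    Used with :func:`average_year` output so that sowings late in the
    virtual year still have a full growing season of (repeated) average
    weather ahead of them.
    """
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    extra_dates = pd.date_range(series.dates[-1] + pd.Timedelta(days=1), periods=n_days, freq="D")
    reps = int(np.ceil(n_days / len(series))) if n_days else 0
    extra_vals = np.tile(series.tmean_c, max(reps, 1))[:n_days]
    return WeatherSeries(
        series.site_id, series.dates.append(extra_dates), np.concatenate([series.tmean_c, extra_vals])
    )


def build_environments(
    sites: Sequence[Site],
    sowing_dates: Sequence[dt.date],
    weather: Mapping[str, WeatherSeries] | Iterable[WeatherSeries],
    horizon_days: int = 300,
) -> list[Environment]:
    """Cross sites with sowing dates into candidate environments.

    ``weather`` maps each site_id to a single (possibly multi-year)
    contiguous series that must cover ``sowing_date .. sowing_date +
    horizon_days − 1``.  Temperature is re-indexed to days after sowing
    and day length computed from the site latitude.
    """
    if not isinstance(weather, Mapping):
        weather = {w.site_id: w for w in weather}
    envs: list[Environment] = []
    for site in sites:
        series = weather.get(site.site_id)
        if series is None:
            raise ValueError(f"no weather series for site {site.site_id!r}")
        for sowing in sowing_dates:
            start = (pd.Timestamp(sowing) - series.dates[0]).days
            if start < 0 or start + horizon_days > len(series):
                raise ValueError(
                    f"weather for site {site.site_id!r} does not cover "
                    f"{sowing} + {horizon_days} days"
                )
            window = series.dates[start : start + horizon_days]
            if (window[0] != pd.Timestamp(sowing)) or (window[-1] - window[0]).days != horizon_days - 1:
                raise ValueError(
                    f"weather for site {site.site_id!r} has gaps after {sowing}"
                )
            envs.append(
                Environment(
                    env_id=f"{site.site_id}:{sowing.isoformat()}",
                    site=site,
                    sowing_date=sowing,
                    tmean_c=series.tmean_c[start : start + horizon_days],
                    daylength_h=_day_length_vector(
                        site.latitude_deg, window.dayofyear.to_numpy()
                    ),
                )
            )
    return envs
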