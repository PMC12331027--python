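"""Weather ingestion, monthly-to-daily disaggregation and thermal time.

All growth functions in this package run on thermal time (growing degree
days, °C·d), accumulated from daily mean temperature above a base
temperature.  Field weather arrives either as daily station records or as
monthly climate summaries; the latter are disaggregated to a synthetic
daily series so the simulator can run on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeather",
    "MonthRecord",
    "MonthlyClimate",
    "ThermalTimeSeries",
    "SeasonSummary",
    "WeatherValidationError",
    "read_weather_csv",
    "disaggregate_monthly",
    "thermal_time",
    "season_summary",
]

#: Default base temperature for potato degree-day accumulation (°C).
DEFAULT_BASE_TEMPERATURE = 2.0


class WeatherValidationError(ValueError):
    """Raised when a weather table violates its physical invariants."""


@dataclass(frozen=True)
class DailyWeather:
    """One day of station weather.

    Parameters
    ----------
    day : int
        Day index since season start (1-based, contiguous).
    tmax, tmin : float
        Daily maximum / minimum air temperature, °C.
    sr : float
        Daily total solar radiation, MJ·m⁻²·d⁻¹.
    rain : float
        Daily rainfall, mm.
    """

    day: int
    tmax: float
    tmin: float
    sr: float
    rain: float

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise WeatherValidationError(
                f"day {self.day}: tmax ({self.tmax}) < tmin ({self.tmin})"
            )
        if self.sr < 0:
            raise WeatherValidationError(f"day {self.day}: negative solar radiation")
        if self.rain < 0:
            raise WeatherValidationError(f"day {self.day}: negative rainfall")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmax + self.tmin)


@dataclass(frozen=True)
class MonthRecord:
    """Monthly climate summary: mean daily extremes, total rain, mean SR."""

    month: str
    tmax: float
    tmin: float
    rain: float  # monthly total, mm
    sr: float    # monthly mean, MJ·m⁻²·d⁻¹
    snh: float | None = None  # sunshine hours, informational

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise WeatherValidationError(
                f"month {self.month}: tmax ({self.tmax}) < tmin ({self.tmin})"
            )
        if self.rain < 0:
            raise WeatherValidationError(f"month {self.month}: negative rainfall")


@dataclass(frozen=True)
class MonthlyClimate:
    """A growing season described by consecutive monthly climate records."""

    season: str
    months: tuple[MonthRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "months", tuple(self.months))

    def __len__(self) -> int:
        return len(self.months)


@dataclass(frozen=True)
class ThermalTimeSeries:
    """Cumulative thermal time (°C·d) per day, zero before the clock origin."""

    day: np.ndarray
    cumulative: np.ndarray
    base_temperature: float
    origin_day: int

    def at_day(self, day: int) -> float:
        idx = np.searchsorted(self.day, day)
        if idx >= len(self.day) or self.day[idx] != day:
            raise KeyError(f"day {day} not in thermal time series")
        return float(self.cumulative[idx])


@dataclass(frozen=True)
class SeasonSummary:
    """Seasonal climate aggregates: rain total, SR mean, temperature ranges."""

    season: str
    total_rainfall: float
    mean_sr: float
    tmax_range: tuple[float, float]
    tmin_range: tuple[float, float]
    tdif_range: tuple[float, float]


_CSV_COLUMNS = ("day", "tmax", "tmin", "sr", "rain")


def read_weather_csv(path) -> list[DailyWeather]:
    """Read a daily weather CSV with columns ``day,tmax,tmin,sr,rain``.

    Records are returned in day order; the day column must be contiguous
    (no gaps).  Any non-numeric cell, missing column, or physically
    impossible row (tmax < tmin, negative SR or rain) raises
    :class:`WeatherValidationError` naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise WeatherValidationError(f"missing column(s): {', '.join(missing)}")
    for col in _CSV_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            raise WeatherValidationError(
                f"non-numeric value in column '{col}' at row {int(bad[0])}"
            )
        df[col] = coerced
    df = df.sort_values("day").reset_index(drop=True)
    days = df["day"].to_numpy()
    if not np.array_equal(days, np.arange(days[0], days[0] + len(days))):
        raise WeatherValidationError("day column has gaps or duplicates")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                DailyWeather(int(row["day"]), row["tmax"], row["tmin"],
                             row["sr"], row["rain"])
            )
        except WeatherValidationError as exc:
            raise WeatherValidationError(f"row {i}: {exc}") from None
    return out


def weather_to_frame(weather: Sequence[DailyWeather]) -> pd.DataFrame:
    """Tabulate a daily weather sequence as a DataFrame."""
    return pd.DataFrame(
        {
            "day": [w.day for w in weather],
            "tmax": [w.tmax for w in weather],
            "tmin": [w.tmin for w in weather],
            "sr": [w.sr for w in weather],
            "rain": [w.rain for w in weather],
        }
    )


def disaggregate_monthly(
    climate: MonthlyClimate,
    days_per_month: int | Sequence[int] = 30,
) -> list[DailyWeather]:
    """Expand a monthly climate into a synthetic daily series.

    Each day of a month carries that month's mean tmax/tmin/SR; the monthly
    rainfall total is split uniformly across the month's days so that
    re-summing per month conserves the monthly totals exactly.
    """
    if len(climate) == 0:
        raise WeatherValidationError("empty climate")
    if isinstance(days_per_month, int):
        days_per_month = [days_per_month] * len(climate)
    if len(days_per_month) != len(climate):
        raise WeatherValidationError(
            "days_per_month must give one day count per month"
        )
    out: list[DailyWeather] = []
    day = 1
    for rec, ndays in zip(climate.months, days_per_month):
        if ndays <= 0:
            raise WeatherValidationError(f"month {rec.month}: non-positive day count")
        daily_rain = rec.rain / ndays
        for _ in range(ndays):
            out.append(DailyWeather(day, rec.tmax, rec.tmin, rec.sr, daily_rain))
            day += 1
    return out


def thermal_time(
    weather: Sequence[DailyWeather],
    base_temperature: float = DEFAULT_BASE_TEMPERATURE,
    origin_day: int | None = None,
) -> ThermalTimeSeries:
    """Accumulate growing degree days over a daily weather series.

    The daily increment is ``max(0, (tmax + tmin)/2 − base_temperature)``;
    accumulation starts at ``origin_day`` (typically crop emergence) and
    days before the origin contribute zero.
    """
    if not math.isfinite(base_temperature):
        raise ValueError("base_temperature must be finite")
    if not weather:
        raise WeatherValidationError("empty weather series")
    days = np.array([w.day for w in weather])
    if origin_day is None:
        origin_day = int(days[0])
    if origin_day < days[0] or origin_day > days[-1]:
        raise ValueError(f"origin_day {origin_day} outside series {days[0]}..{days[-1]}")
    inc = np.array(
        [max(0.0, w.tmean - base_temperature) for w in weather]
    )
    inc[days < origin_day] = 0.0
    return ThermalTimeSeries(
        day=days,
        cumulative=np.cumsum(inc),
        base_temperature=base_temperature,
        origin_day=origin_day,
    )


def season_summary(climate: MonthlyClimate) -> SeasonSummary:
    """Aggregate a monthly climate: total rain, mean SR, temperature ranges.

    Mean SR is the unweighted mean of the monthly values; the diurnal
    range (Tdif) is computed as tmax − tmin per month.
    """
    if len(climate) == 0:
        raise WeatherValidationError("empty climate")
    tmax = np.array([m.tmax for m in climate.months])
    tmin = np.array([m.tmin for m in climate.months])
    rain = np.array([m.rain for m in climate.months])
    sr = np.array([m.sr for m in climate.months])
    tdif = tmax - tmin
    return SeasonSummary(
        season=climate.season,
        total_rainfall=float(rain.sum()),
        mean_sr=float(sr.mean()),
        tmax_range=(float(tmax.min()), float(tmax.max())),
        tmin_range=(float(tmin.min()), float(tmin.max())),
        tdif_range=(float(tdif.min()), float(tdif.max())),
    )
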