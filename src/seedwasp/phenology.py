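"""Degree-day accumulation and the Weibull cumulative-emergence model.

Daily heat units above the lower threshold LT, capped at the upper threshold
UT, are accumulated from a 1 January biofix.  The fraction of the population
that has completed post-diapause development by accumulated degree days x is
modelled with a two-parameter Weibull distribution

    F(x) = 1 - exp(-(x/a)^b)

with scale a (degree days) and shape b.  Mapping predicted quantiles of F
through a season's cumulative degree-day series yields calendar dates for the
10-90% cumulative-flight points.

The single-day degree-day rule is the "modified average" method: the daily
mean of max/min temperatures with the min raised to LT and the max lowered to
UT before averaging, zero when the maximum never reaches LT, and never more
than UT - LT.  Boundary ties go to the cooler case so the rule is continuous
in both temperatures.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import FitFailureError, PreconditionError, WeatherGapError

__all__ = [
    "DailyWeather", "DDSeries", "WeibullPhenology", "FlightPrediction",
    "weibull_cdf", "weibull_quantile", "fit_weibull",
    "dd_constant", "dd_daily", "accumulate_dd", "predict_flight_dates",
    "read_weather_csv", "write_weather_csv", "predictions_to_csv",
]

DEFAULT_LT = 7.3   # degC, adult-exit lower threshold from the linear model
DEFAULT_UT = 34.3  # degC, upper threshold at which development fails
DEFAULT_POINTS = (0.10, 0.30, 0.50, 0.70, 0.90)


class DailyWeather(NamedTuple):
    """One day of station weather: calendar date, max and min temperature."""

    date: dt.date
    tmax: float
    tmin: float


@dataclass(frozen=True)
class WeibullPhenology:
    """Fitted two-parameter Weibull phenology for one stage or sex."""

    a: float                 # scale, degree days
    b: float                 # shape, dimensionless
    stage: str = "adult_exit"
    r2: float = float("nan")

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("Weibull scale and shape must be positive")

    def cdf(self, x):
        return weibull_cdf(x, self.a, self.b)

    def quantile(self, q):
        return weibull_quantile(q, self.a, self.b)


@dataclass(frozen=True)
class DDSeries:
    """Dated daily and cumulative degree days from a biofix."""

    biofix: dt.date
    dates: tuple[dt.date, ...]
    dd: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self):
        if np.any(self.dd < 0):
            raise ValueError("daily degree days cannot be negative")
        if np.any(np.diff(self.cumulative) < -1e-9):
            raise ValueError("cumulative degree days must be nondecreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": list(self.dates), "dd": self.dd,
                             "cumulative_dd": self.cumulative})


class FlightPrediction(NamedTuple):
    proportion: float
    date: dt.date | None      # None when the series never reaches the point
    julian_day: int | None
    cumulative_dd: float
    reached: bool


def weibull_cdf(x, a: float, b: float):
    """Cumulative proportion developed at accumulated degree days x."""
    if not (a > 0 and b > 0):
        raise PreconditionError("Weibull scale and shape must be positive")
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise PreconditionError("accumulated degree days cannot be negative")
    out = 1.0 - np.exp(-((x_arr / a) ** b))
    return out if np.ndim(x) else float(out)


def weibull_quantile(q, a: float, b: float):
    """Degree days at which the cumulative proportion reaches q."""
    q_arr = np.asarray(q, dtype=float)
    if np.any((q_arr <= 0) | (q_arr >= 1)):
        raise PreconditionError("quantile must lie strictly in (0, 1)")
    out = a * (-np.log1p(-q_arr)) ** (1.0 / b)
    return out if np.ndim(q) else float(out)


def fit_weibull(
    points: Iterable[tuple[float, float]],
    stage: str = "adult_exit",
) -> WeibullPhenology:
    """Least-squares Weibull fit to (cumulative DD, cumulative proportion).

    Initialised from the Weibull-plot linearisation
    ln(-ln(1 - F)) = b ln x - b ln a on the interior points, then refined by
    damped least squares on the CDF itself.
    """
    pts = [(float(x), float(f)) for x, f in points]
    if len(pts) < 3:
        raise PreconditionError("need >= 3 (degree day, proportion) points")
    x = np.array([p[0] for p in pts])
    f = np.array([p[1] for p in pts])
    if np.any((f < 0) | (f > 1)):
        raise PreconditionError("proportions must lie in [0, 1]")
    if np.any(x < 0):
        raise PreconditionError("accumulated degree days cannot be negative")
    if np.ptp(f) == 0:
        raise FitFailureError("all proportions equal; Weibull fit is degenerate")

    interior = (f > 1e-9) & (f < 1 - 1e-9) & (x > 0)
    if interior.sum() >= 2:
        ly = np.log(-np.log1p(-f[interior]))
        lx = np.log(x[interior])
        b0, c0 = np.polyfit(lx, ly, 1)
        b0 = float(np.clip(b0, 0.05, 100.0))
        a0 = float(np.exp(-c0 / b0))
    else:
        a0, b0 = float(np.median(x[x > 0])) or 1.0, 5.0

    def residuals(theta):
        a, b = theta
        return 1.0 - np.exp(-((x / a) ** b)) - f

    sol = optimize.least_squares(
        residuals, x0=[a0, b0], bounds=([1e-6, 1e-3], [1e6, 1e3]),
        method="trf", xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise FitFailureError(f"Weibull fit did not converge: {sol.message}")
    rss = float(sol.fun @ sol.fun)
    tss = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return WeibullPhenology(a=float(sol.x[0]), b=float(sol.x[1]),
                            stage=stage, r2=r2)


def dd_constant(Ta: float, LT: float, days: float) -> float:
    """Degree days accrued over ``days`` at constant temperature Ta."""
    if days < 0:
        raise PreconditionError("days cannot be negative")
    return max(Ta - LT, 0.0) * days


def dd_daily(tmax: float, tmin: float, LT: float = DEFAULT_LT,
             UT: float = DEFAULT_UT) -> float:
    """Degree days for one day from its max/min temperatures.

    Cases: 0 when tmax <= LT; otherwise the mean of (tmax capped at UT) and
    (tmin raised to LT) minus LT, clamped to [0, UT - LT].  This reproduces
    the classic piecewise rules — (tmax+LT)/2 - LT when the minimum is below
    threshold, (tmax+tmin)/2 - LT in the interior, (UT+tmin)/2 - LT when the
    maximum exceeds UT — and fills the two remaining corners ((UT+LT)/2 - LT
    when both bounds are exceeded; UT - LT when even the minimum tops UT) by
    continuity.
    """
    if LT >= UT:
        raise PreconditionError("lower threshold must be below upper threshold")
    if tmax < tmin:
        raise PreconditionError("tmax must be >= tmin")
    if tmax <= LT:
        return 0.0
    dd = (min(tmax, UT) + max(tmin, LT)) / 2.0 - LT
    return float(np.clip(dd, 0.0, UT - LT))


def _as_weather(weather) -> list[DailyWeather]:
    if isinstance(weather, pd.DataFrame):
        return [DailyWeather(pd.Timestamp(r.date).date(), float(r.tmax_c), float(r.tmin_c))
                for r in weather.itertuples()]
    out = []
    for w in weather:
        if isinstance(w, DailyWeather):
            out.append(w)
        else:
            d, tx, tn = w
            out.append(DailyWeather(pd.Timestamp(d).date(), float(tx), float(tn)))
    return out


def accumulate_dd(
    weather,
    LT: float = DEFAULT_LT,
    UT: float = DEFAULT_UT,
    biofix: dt.date | str | None = None,
) -> DDSeries:
    """Accumulate daily degree days from the biofix (default 1 January).

    ``weather`` is a DataFrame (date, tmax_c, tmin_c) or an iterable of
    :class:`DailyWeather`; it must cover the biofix onward without gaps.
    """
    days = sorted(_as_weather(weather), key=lambda w: w.date)
    if not days:
        raise PreconditionError("weather series is empty")
    if biofix is None:
        biofix = dt.date(days[0].date.year, 1, 1)
    elif isinstance(biofix, str):
        biofix = pd.Timestamp(biofix).date()
    days = [w for w in days if w.date >= biofix]
    if not days or days[0].date != biofix:
        raise WeatherGapError(biofix)
    for prev, cur in zip(days, days[1:]):
        if (cur.date - prev.date).days != 1:
            raise WeatherGapError(prev.date + dt.timedelta(days=1))
    dd = np.array([dd_daily(w.tmax, w.tmin, LT, UT) for w in days])
    return DDSeries(biofix=biofix, dates=tuple(w.date for w in days),
                    dd=dd, cumulative=np.cumsum(dd))


def predict_flight_dates(
    dds: DDSeries,
    model: WeibullPhenology,
    points: Sequence[float] = DEFAULT_POINTS,
) -> list[FlightPrediction]:
    """Calendar dates at which predicted cumulative flight reaches each point.

    For each proportion q the first day whose cumulative degree days x gives
    F(x) >= q is returned (no within-day interpolation, matching integer
    Julian dates).  Points the series never reaches are flagged unreached.
    """
    out = []
    cdf = model.cdf(dds.cumulative)
    for q in points:
        if not 0 < q < 1:
            raise PreconditionError("cumulative points must lie in (0, 1)")
        idx = np.searchsorted(cdf, q, side="left")
        if idx >= len(cdf):
            out.append(FlightPrediction(q, None, None,
                                        float(dds.cumulative[-1]), False))
        else:
            date = dds.dates[idx]
            out.append(FlightPrediction(q, date, date.timetuple().tm_yday,
                                        float(dds.cumulative[idx]), True))
    return out


# --- CSV interface --------------------------------------------------------

def read_weather_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = {"date", "tmax_c", "tmin_c"} - set(df.columns)
    if missing:
        raise PreconditionError(f"{path}: weather CSV missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if np.any(df["tmax_c"] < df["tmin_c"]):
        raise PreconditionError(f"{path}: tmax_c below tmin_c")
    return df


def write_weather_csv(weather, path: str | Path) -> None:
    rows = _as_weather(weather)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["date", "tmax_c", "tmin_c"])
        for day in rows:
            w.writerow([day.date.isoformat(), f"{day.tmax:.2f}", f"{day.tmin:.2f}"])


def predictions_to_csv(preds: Iterable[FlightPrediction], path: str | Path,
                       header_comment: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh)
        w.writerow(["proportion", "date", "julian_day", "cumulative_dd", "reached"])
        for p in preds:
            w.writerow([p.proportion,
                        p.date.isoformat() if p.date else "",
                        p.julian_day if p.julian_day is not None else "",
                        f"{p.cumulative_dd:.2f}", int(p.reached)])
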