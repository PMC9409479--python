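"""Validation statistics for emergence forecasts, plus data-hygiene helpers.

A forecast is judged against daily trap counts of exiting adults: the
observed season is reduced to the Julian dates at which cumulative flight
first reaches the 10/30/50/70/90% points, and compared with the model's
predicted dates through

* the mean +/- SE of the absolute day differences,
* one-tailed one-sample t-tests of whether that mean exceeds 3 or 5 days,
* Pearson's correlation between observed and predicted dates.

Also here: the post-emergence interval (adults resting inside the seed
between emergence from the pupa and exit through the hole) as a difference of
stage means, and a single-pass Grubbs screen for outlying durations.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PreconditionError
from .phenology import DEFAULT_POINTS

__all__ = [
    "FlightObservation", "ValidationReport", "TTestResult",
    "observed_flight_dates", "mean_abs_diff", "one_sample_t_onetailed",
    "pearson_r", "post_emergence_days", "grubbs_screen",
    "build_validation_report", "report_to_csv",
    "read_counts_csv", "write_counts_csv",
]


class FlightObservation(NamedTuple):
    """Daily trap record: adults exiting on one date."""

    date: dt.date
    count: int


class TTestResult(NamedTuple):
    t: float
    p: float
    computable: bool


@dataclass
class ValidationReport:
    """One site-year of forecast accuracy, mirroring the field-trial layout."""

    label: str
    points: tuple[float, ...]
    observed_dates: tuple[int, ...]      # Julian days
    predicted_dates: tuple[int, ...]
    mean_abs_diff: float
    se: float
    t3: TTestResult
    t5: TTestResult
    pearson_r: float


def _to_date(d) -> dt.date:
    return d if isinstance(d, dt.date) else pd.Timestamp(d).date()


def observed_flight_dates(
    obs: Iterable[FlightObservation | tuple],
    points: Sequence[float] = DEFAULT_POINTS,
) -> list[tuple[float, dt.date]]:
    """First date on which cumulative observed flight reaches each point."""
    recs = sorted(
        ((_to_date(o[0]), float(o[1])) for o in obs), key=lambda r: r[0])
    counts = np.array([c for _, c in recs])
    if np.any(counts < 0):
        raise PreconditionError("counts cannot be negative")
    total = counts.sum()
    if total <= 0:
        raise PreconditionError("no adults observed: total count is zero")
    cum = np.cumsum(counts) / total
    out = []
    for q in points:
        if not 0 < q <= 1:
            raise PreconditionError("cumulative points must lie in (0, 1]")
        idx = int(np.searchsorted(cum, q - 1e-12, side="left"))
        out.append((q, recs[idx][0]))
    return out


def _abs_diffs(observed, predicted) -> np.ndarray:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise PreconditionError("observed and predicted must have equal length")
    if o.size < 2:
        raise PreconditionError("need at least two paired dates")
    return np.abs(o - p)


def mean_abs_diff(observed, predicted) -> tuple[float, float]:
    """Mean and standard error of |observed - predicted| in days."""
    d = _abs_diffs(observed, predicted)
    return float(d.mean()), float(d.std(ddof=1) / math.sqrt(d.size))


def one_sample_t_onetailed(diffs, mu0: float) -> TTestResult:
    """Upper-tailed one-sample t-test of mean(diffs) > mu0.

    When every difference is identical the statistic is undefined (zero
    standard deviation) and the result is flagged not-computable.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise PreconditionError("need at least two differences")
    sd = d.std(ddof=1)
    if sd == 0:
        return TTestResult(math.nan, math.nan, False)
    t = (d.mean() - mu0) / (sd / math.sqrt(d.size))
    p = float(stats.t.sf(t, df=d.size - 1))
    return TTestResult(float(t), p, True)


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise PreconditionError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PreconditionError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def post_emergence_days(mean_total_exit: float, mean_total_emergence: float) -> float:
    """Days adults spend inside the seed after emergence, as a difference of
    the mean exit and mean emergence durations at one temperature."""
    if mean_total_exit <= 0 or mean_total_emergence <= 0:
        raise PreconditionError("mean durations must be positive")
    diff = mean_total_exit - mean_total_emergence
    if diff < 0:
        warnings.warn(
            "exit duration below emergence duration is biologically impossible",
            RuntimeWarning, stacklevel=2)
    return diff


def grubbs_screen(values, alpha: float = 0.05) -> tuple[int | None, float]:
    """Two-sided Grubbs test for a single outlier.

    Returns (index of the flagged value or None, G statistic), where
    G = max|x - mean| / s and the critical value is
    ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper alpha/(2n)
    quantile of Student's t on n-2 df.  One pass flags at most one value;
    call repeatedly to strip several.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise PreconditionError("Grubbs test needs n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        return None, 0.0
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    G = float(dev[i] / s)
    n = x.size
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
    return (i, G) if G > crit else (None, G)


def build_validation_report(
    observed_dates: Sequence[int],
    predicted_dates: Sequence[int],
    label: str = "",
    points: Sequence[float] = DEFAULT_POINTS,
) -> ValidationReport:
    """Full accuracy summary for one site-year of paired Julian dates."""
    d = _abs_diffs(observed_dates, predicted_dates)
    mean, se = mean_abs_diff(observed_dates, predicted_dates)
    return ValidationReport(
        label=label,
        points=tuple(points),
        observed_dates=tuple(int(v) for v in observed_dates),
        predicted_dates=tuple(int(v) for v in predicted_dates),
        mean_abs_diff=mean,
        se=se,
        t3=one_sample_t_onetailed(d, 3.0),
        t5=one_sample_t_onetailed(d, 5.0),
        pearson_r=pearson_r(observed_dates, predicted_dates),
    )


def report_to_csv(reports: Iterable[ValidationReport], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "point", "observed_julian", "predicted_julian",
                    "mean_abs_diff", "se", "t_vs_3", "p_vs_3", "t_vs_5",
                    "p_vs_5", "pearson_r"])
        for r in reports:
            for q, o, p in zip(r.points, r.observed_dates, r.predicted_dates):
                w.writerow([
                    r.label, q, o, p, f"{r.mean_abs_diff:.2f}", f"{r.se:.2f}",
                    f"{r.t3.t:.2f}" if r.t3.computable else "-",
                    f"{r.t3.p:.4f}" if r.t3.computable else "-",
                    f"{r.t5.t:.2f}" if r.t5.computable else "-",
                    f"{r.t5.p:.4f}" if r.t5.computable else "-",
                    f"{r.pearson_r:.4f}"])


def read_counts_csv(path: str | Path) -> list[FlightObservation]:
    df = pd.read_csv(path, comment="#")
    missing = {"date", "count"} - set(df.columns)
    if missing:
        raise PreconditionError(f"{path}: counts CSV missing columns {sorted(missing)}")
    return [FlightObservation(pd.Timestamp(r.date).date(), int(r.count))
            for r in df.itertuples()]


def write_counts_csv(obs: Iterable[FlightObservation], path: str | Path,
                     header_comment: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh)
        w.writerow(["date", "count"])
        for o in obs:
            w.writerow([o.date.isoformat(), o.count])
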