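"""Synthetic study generator: durations, weather, and trap counts.

No raw per-individual data were ever released for the seed wasp study this
package models, so the pipeline is exercised on simulated inputs whose
structure matches the real design:

* constant-temperature rearing cohorts at the seven experimental
  temperatures (14.5-34.3 degC) with per-individual stage durations drawn
  around the reciprocal of a true rate model, lognormal noise, sexes, and
  prolonged-diapause / mortality fates (all development suspended where the
  true rate is nonpositive, as observed at 34.3 degC);
* a year of daily max/min station weather built from a sinusoidal annual
  cycle plus Gaussian noise;
* daily cone-trap counts of exiting adults obtained by inverse-CDF sampling
  individual exit degree-days from a true Weibull phenology and mapping them
  through the weather's cumulative degree-day series.

Everything is driven by one numpy Generator seed and is bit-reproducible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import rate_models
from .errors import PreconditionError
from .fitting import DurationRecord
from .phenology import DailyWeather, WeibullPhenology, accumulate_dd
from .validation import FlightObservation

__all__ = ["GeneratorConfig", "generate_durations", "generate_weather",
           "generate_flight_counts", "generate_study"]

# True rate model per stage.  A 2-tuple of floats is shorthand for the
# linear model written as (LT degC, DD degree days); otherwise give
# (model_name, params).  Defaults match the published post-diapause
# linear estimates.
_DEFAULT_STAGE_TRUTH: Mapping[str, tuple] = {
    "larva": (8.1, 66.2),
    "pupa": (8.2, 180.8),
    "larva_to_exit": (7.3, 336.7),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults reproduce the real experiment: seven rearing temperatures of
    which the hottest halts development, cohort sizes in the tens per
    temperature, a few percent prolonged diapause and mortality, a roughly
    even sex ratio, an 8% coefficient of variation on individual durations,
    a southern-Korea annual temperature cycle, and the published adult-exit
    Weibull phenology as the true emergence distribution.
    """

    stage_truth: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_STAGE_TRUTH))
    temperatures: Sequence[float] = (14.5, 18.8, 21.3, 24.0, 27.0, 30.2, 34.3)
    n_per_temperature: int = 60
    duration_cv: float = 0.08
    prolonged_prob: float = 0.03
    mortality_prob: float = 0.05
    male_prob: float = 0.5
    weather_mean: float = 13.0        # annual mean temperature, degC
    weather_amplitude: float = 10.5   # seasonal half-swing, degC
    diurnal_half_range: float = 4.0   # (tmax - tmin)/2, degC
    weather_noise_sd: float = 2.0     # independent daily noise, degC
    peak_doy: int = 196               # warmest day of year (mid-July)
    upper_threshold: float = 34.3     # degC; development suspends at/above it
    weibull_a: float = 344.9728       # true adult-exit scale, degree days
    weibull_b: float = 13.5357        # true adult-exit shape
    cohort: int = 1000
    seed: int = 20220722

    def __post_init__(self):
        for p in (self.prolonged_prob, self.mortality_prob, self.male_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.cohort <= 0:
            raise ValueError("cohort must be positive")
        if self.duration_cv < 0:
            raise ValueError("duration CV cannot be negative")

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def _true_rate(truth, T: float) -> float:
    """Evaluate a stage truth: (LT, DD) linear shorthand or (model, params)."""
    first, second = truth
    if isinstance(first, str):
        return float(rate_models.evaluate_rate(first, second, T))
    lt, dd = float(first), float(second)
    return (T - lt) / dd


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def generate_durations(cfg: GeneratorConfig) -> list[DurationRecord]:
    """Simulate both rearing designs at every configured temperature.

    Returns cracked-seed individuals (larva + pupa durations, total =
    emergence) followed by intact-seed individuals (total = adult exit).
    Where the true total rate is nonpositive, or at/above the configured
    upper threshold, every developing individual becomes 'prolonged' —
    durations are never infinite.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[DurationRecord] = []
    stage_truth = dict(cfg.stage_truth)
    truth_exit = stage_truth["larva_to_exit"]
    has_stages = "larva" in stage_truth and "pupa" in stage_truth

    for kind in ("emergence", "exit"):
        for T in cfg.temperatures:
            for i in range(cfg.n_per_temperature):
                rid = f"{kind[:2]}-{T:g}-{i:03d}"
                sex = "male" if rng.random() < cfg.male_prob else "female"
                u = rng.random()
                if u < cfg.mortality_prob:
                    records.append(DurationRecord(rid, T, sex=sex, fate="dead",
                                                  kind=kind))
                    continue
                rate_total = _true_rate(truth_exit, T)
                prolonged = (u < cfg.mortality_prob + cfg.prolonged_prob
                             or rate_total <= 1e-6
                             or T >= cfg.upper_threshold)
                if prolonged:
                    records.append(DurationRecord(rid, T, sex=sex,
                                                  fate="prolonged", kind=kind))
                    continue
                if kind == "emergence" and has_stages:
                    r_l = _true_rate(stage_truth["larva"], T)
                    r_p = _true_rate(stage_truth["pupa"], T)
                    if min(r_l, r_p) <= 1e-6:
                        records.append(DurationRecord(rid, T, sex=sex,
                                                      fate="prolonged", kind=kind))
                        continue
                    larva = (1.0 / r_l) * _lognormal_factor(rng, cfg.duration_cv)
                    pupa = (1.0 / r_p) * _lognormal_factor(rng, cfg.duration_cv)
                    records.append(DurationRecord(
                        rid, T, larva_days=float(larva), pupa_days=float(pupa),
                        total_days=float(larva + pupa), sex=sex,
                        fate="emerged", kind=kind))
                else:
                    total = (1.0 / rate_total) * _lognormal_factor(rng, cfg.duration_cv)
                    records.append(DurationRecord(
                        rid, T, total_days=float(total), sex=sex,
                        fate="exited", kind=kind))
    return records


def generate_weather(cfg: GeneratorConfig, year: int) -> list[DailyWeather]:
    """One calendar year of daily max/min temperatures.

    Daily mean follows mean + amplitude * cos(2*pi*(doy - peak)/365); max and
    min sit a diurnal half-range either side plus independent Gaussian noise,
    swapped if noise inverts them.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, year]))
    start = dt.date(year, 1, 1)
    ndays = (dt.date(year + 1, 1, 1) - start).days
    doy = np.arange(1, ndays + 1)
    tmid = cfg.weather_mean + cfg.weather_amplitude * np.cos(
        2 * np.pi * (doy - cfg.peak_doy) / 365.0)
    noise = rng.normal(0.0, cfg.weather_noise_sd, size=(2, ndays)) \
        if cfg.weather_noise_sd > 0 else np.zeros((2, ndays))
    tmax = tmid + cfg.diurnal_half_range + noise[0]
    tmin = tmid - cfg.diurnal_half_range + noise[1]
    swap = tmax < tmin
    tmax[swap], tmin[swap] = tmin[swap], tmax[swap].copy()
    return [DailyWeather(start + dt.timedelta(days=int(d - 1)),
                         float(tx), float(tn))
            for d, tx, tn in zip(doy, tmax, tmin)]


def generate_flight_counts(
    weather: Sequence[DailyWeather],
    LT: float,
    UT: float,
    weibull_true: WeibullPhenology,
    cohort: int,
    seed: int,
) -> tuple[list[FlightObservation], int]:
    """Daily exit counts from a cohort with Weibull-distributed exit DD.

    Each individual draws an exit degree-day requirement by inverse-CDF
    sampling and exits on the first day the cumulative series reaches it.
    Returns (daily counts, number whose requirement the season never met).
    """
    if cohort <= 0:
        raise PreconditionError("cohort must be positive")
    rng = np.random.default_rng(seed)
    dds = accumulate_dd(weather, LT=LT, UT=UT)
    u = rng.random(cohort)
    exit_dd = weibull_true.quantile(np.clip(u, 1e-12, 1 - 1e-12))
    idx = np.searchsorted(dds.cumulative, exit_dd, side="left")
    unemerged = int(np.sum(idx >= len(dds.cumulative)))
    counts = np.bincount(idx[idx < len(dds.cumulative)],
                         minlength=len(dds.cumulative))
    obs = [FlightObservation(d, int(c))
           for d, c in zip(dds.dates, counts) if c > 0]
    return obs, unemerged


def generate_study(cfg: GeneratorConfig, year: int = 2022):
    """Full synthetic study: durations, weather, and trap counts."""
    durations = generate_durations(cfg)
    weather = generate_weather(cfg, year)
    truth_exit = cfg.stage_truth["larva_to_exit"]
    lt = float(truth_exit[0]) if not isinstance(truth_exit[0], str) else 7.3
    counts, unemerged = generate_flight_counts(
        weather, LT=lt, UT=cfg.upper_threshold,
        weibull_true=WeibullPhenology(cfg.weibull_a, cfg.weibull_b),
        cohort=cfg.cohort, seed=cfg.seed + 1)
    return durations, weather, counts, unemerged
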