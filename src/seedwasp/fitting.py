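"""Fitting the candidate rate models to duration data.

Rates are reciprocal durations of individuals reared at constant temperature.
The two linear estimators are ordinary least squares of rate on temperature
and the Ikemoto-Takai regression of D*T on duration D, whose slope and
intercept are directly the lower threshold and the thermal constant.  The
eight nonlinear curves are fitted by damped (Levenberg-Marquardt-type) least
squares restarted from a Latin-hypercube of initial points inside each
model's parameter bounds; the lowest-RSS converged solution wins.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from . import rate_models
from .errors import FitFailureError, PreconditionError, SingularDesignError
from .rate_models import RateModelSpec, ThermalTraits

__all__ = [
    "RateObservation",
    "DurationRecord",
    "FitResult",
    "fit_ordinary_linear",
    "fit_ikemoto",
    "fit_nonlinear",
    "fit_all_models",
    "rates_from_records",
    "read_durations_csv",
    "write_durations_csv",
]

MULTISTART_SEED = 20220722
N_STARTS = 50

STAGES = ("larva", "pupa", "larva_to_emergence", "larva_to_exit")


@dataclass(frozen=True)
class RateObservation:
    """One (temperature, development rate) point for a stage and sex group."""

    temperature: float
    rate: float
    stage: str = "larva_to_exit"
    group: str = "all"

    def __post_init__(self):
        if not self.rate > 0:
            raise ValueError("development rate must be positive")


@dataclass
class DurationRecord:
    """Per-individual outcome of one rearing at constant temperature.

    ``larva_days``/``pupa_days`` are only known in the cracked-seed design
    (``kind='emergence'``, total runs to adult emergence); the intact-seed
    design (``kind='exit'``) observes only the total until adult exit.  Fate
    'prolonged' marks live larvae that never pupated (prolonged diapause);
    prolonged and dead individuals have no completed duration.
    """

    id: str
    temperature: float
    larva_days: float | None = None
    pupa_days: float | None = None
    total_days: float | None = None
    sex: str = "unknown"
    fate: str = "emerged"
    kind: str = "exit"

    def __post_init__(self):
        for v in (self.larva_days, self.pupa_days, self.total_days):
            if v is not None and v <= 0:
                raise ValueError("durations must be positive where present")
        if (self.total_days is not None and self.larva_days is not None
                and self.pupa_days is not None
                and self.total_days + 1e-9 < self.larva_days + self.pupa_days):
            raise ValueError("total duration must be >= sum of its stages")


@dataclass
class FitResult:
    """Outcome of fitting one model: parameters plus goodness-of-fit."""

    model: str
    params: np.ndarray
    n: int
    p: int
    rss: float
    adj_r2: float
    temperature_range: tuple[float, float]
    traits: ThermalTraits | None = field(default=None, compare=False)

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.rss < 0:
            raise ValueError("RSS cannot be negative")
        if self.p >= self.n:
            raise ValueError("need more observations than parameters")


def _as_xy(obs: Iterable) -> tuple[np.ndarray, np.ndarray]:
    T, r = [], []
    for o in obs:
        if isinstance(o, RateObservation):
            T.append(o.temperature)
            r.append(o.rate)
        else:
            t_i, r_i = o
            T.append(float(t_i))
            r.append(float(r_i))
    return np.asarray(T, dtype=float), np.asarray(r, dtype=float)


def _gof(y: np.ndarray, resid: np.ndarray, p: int) -> tuple[float, float]:
    rss = float(resid @ resid)
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0 or n - p <= 0:
        return rss, np.nan
    adj_r2 = 1.0 - (rss / (n - p)) / (tss / (n - 1))
    return rss, adj_r2


def fit_ordinary_linear(obs: Iterable) -> FitResult:
    """OLS of rate on temperature; LT = -b/a, DD = 1/a.

    ``obs`` may be RateObservation objects or (temperature, rate) pairs.
    """
    T, y = _as_xy(obs)
    if len(T) < 3 or len(np.unique(T)) < 2:
        if len(np.unique(T)) < 2:
            raise SingularDesignError("all temperatures identical")
        raise PreconditionError("need >= 3 observations at >= 2 temperatures")
    X = np.column_stack([T, np.ones_like(T)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b = coef
    rss, adj_r2 = _gof(y, y - X @ coef, 2)
    res = FitResult("ordinary_linear", coef, len(T), 2, rss, adj_r2,
                    (float(T.min()), float(T.max())))
    res.traits = rate_models.thermal_traits("ordinary_linear", coef)
    return res


def fit_ikemoto(durations: Iterable[tuple[float, float]]) -> FitResult:
    """Ikemoto-Takai linear estimator on (temperature, duration) pairs.

    Regresses D*T on D; the slope estimates the lower threshold Tmin and the
    intercept the thermal constant K.
    """
    pairs = [(float(t), float(d)) for t, d in durations]
    if len(pairs) < 3:
        raise PreconditionError("need >= 3 (temperature, duration) points")
    T = np.array([t for t, _ in pairs])
    D = np.array([d for _, d in pairs])
    if len(np.unique(D)) < 2:
        raise SingularDesignError("all durations identical")
    X = np.column_stack([D, np.ones_like(D)])
    y = D * T
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    tmin, K = coef
    rss, adj_r2 = _gof(y, y - X @ coef, 2)
    res = FitResult("ikemoto", np.array([K, tmin]), len(D), 2, rss, adj_r2,
                    (float(T.min()), float(T.max())))
    res.traits = rate_models.thermal_traits("ikemoto", res.params)
    return res


def _lhs_starts(spec: RateModelSpec, n_starts: int, seed: int) -> np.ndarray:
    sampler = qmc.LatinHypercube(d=spec.n_params, seed=seed)
    unit = sampler.random(n=n_starts)
    lo = np.array([b[0] for b in spec.param_bounds])
    hi = np.array([b[1] for b in spec.param_bounds])
    return qmc.scale(unit, lo, hi)


def fit_nonlinear(
    spec: RateModelSpec | str,
    obs: Iterable,
    starts: np.ndarray | None = None,
    n_starts: int = N_STARTS,
    seed: int = MULTISTART_SEED,
) -> FitResult:
    """Multi-start damped least squares for one nonlinear rate model.

    Each start runs a trust-region damped least-squares minimisation of the
    residual sum of squares, bounded by the model's parameter box; the best
    converged solution is returned.  Raises :class:`FitFailureError` with
    per-start diagnostics when nothing converges.
    """
    if isinstance(spec, str):
        spec = rate_models.get_model(spec)
    T, y = _as_xy(obs)
    if len(T) <= spec.n_params:
        raise PreconditionError(
            f"{spec.name}: need n > p ({len(T)} observations, {spec.n_params} parameters)")
    if starts is None:
        starts = _lhs_starts(spec, n_starts, seed)
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    lo = np.array([b[0] for b in spec.param_bounds])
    hi = np.array([b[1] for b in spec.param_bounds])

    def residuals(params):
        r = spec._fn(T, *params)
        return r - y

    best = None
    diagnostics = []
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-12)
        except (ValueError, FloatingPointError, ZeroDivisionError,
                PreconditionError) as exc:
            diagnostics.append({"x0": x0.tolist(), "error": str(exc)})
            continue
        if not sol.success or not np.all(np.isfinite(sol.x)):
            diagnostics.append({"x0": x0.tolist(), "status": sol.status,
                                "message": sol.message})
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError(f"{spec.name}: no start converged", diagnostics)
    rss, adj_r2 = _gof(y, best.fun, spec.n_params)
    res = FitResult(spec.name, best.x, len(T), spec.n_params, rss, adj_r2,
                    (float(T.min()), float(T.max())))
    try:
        res.traits = rate_models.thermal_traits(spec, best.x)
    except ValueError:
        res.traits = None
    return res


def fit_all_models(
    obs: Iterable,
    durations: Iterable[tuple[float, float]] | None = None,
    models: Sequence[str] = rate_models.MODEL_NAMES,
    seed: int = MULTISTART_SEED,
) -> list[FitResult]:
    """Fit every named candidate; failed nonlinear fits are skipped.

    ``durations`` feeds the Ikemoto estimator (it regresses on durations, not
    rates); when omitted, durations are taken as reciprocal rates.
    """
    obs = list(obs)
    T, y = _as_xy(obs)
    if durations is None:
        durations = list(zip(T, 1.0 / y))
    results = []
    for name in models:
        spec = rate_models.get_model(name)
        if name == "ordinary_linear":
            results.append(fit_ordinary_linear(obs))
        elif name == "ikemoto":
            results.append(fit_ikemoto(durations))
        else:
            try:
                results.append(fit_nonlinear(spec, obs, seed=seed))
            except FitFailureError:
                continue
    return results


def rates_from_records(
    records: Iterable[DurationRecord],
    stage: str = "larva_to_exit",
    group: str = "all",
) -> list[RateObservation]:
    """Convert individual durations to rate observations for one stage.

    Individuals with fate 'prolonged' or 'dead' carry no completed duration
    and are excluded.  ``group`` filters by sex ('all', 'male', 'female').
    """
    if stage not in STAGES:
        raise PreconditionError(f"unknown stage {stage!r}")
    attr = {"larva": "larva_days", "pupa": "pupa_days",
            "larva_to_emergence": "total_days", "larva_to_exit": "total_days"}[stage]
    kind = {"larva": "emergence", "pupa": "emergence",
            "larva_to_emergence": "emergence", "larva_to_exit": "exit"}[stage]
    out = []
    for rec in records:
        if rec.fate in ("prolonged", "dead") or rec.kind != kind:
            continue
        if group != "all" and rec.sex != group:
            continue
        d = getattr(rec, attr)
        if d is None:
            continue
        out.append(RateObservation(rec.temperature, 1.0 / d, stage=stage, group=group))
    return out


# --- CSV interface (long format: one row per stage per individual) --------

_CSV_HEADER = ["id", "temperature_c", "stage", "duration_days", "sex", "fate"]
_STAGE_ATTR = {"larva": "larva_days", "pupa": "pupa_days",
               "larva_to_emergence": "total_days", "larva_to_exit": "total_days"}


def _total_stage(rec: DurationRecord) -> str:
    return "larva_to_emergence" if rec.kind == "emergence" else "larva_to_exit"


def write_durations_csv(records: Iterable[DurationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_HEADER)
        for rec in records:
            wrote = False
            for stage, attr in (("larva", "larva_days"), ("pupa", "pupa_days"),
                                (_total_stage(rec), "total_days")):
                d = getattr(rec, attr)
                if d is not None:
                    w.writerow([rec.id, rec.temperature, stage, d, rec.sex, rec.fate])
                    wrote = True
            if not wrote:  # prolonged/dead individuals keep a placeholder row
                w.writerow([rec.id, rec.temperature, _total_stage(rec), "",
                            rec.sex, rec.fate])


def read_durations_csv(path: str | Path) -> list[DurationRecord]:
    by_id: dict[tuple[str, float], DurationRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_CSV_HEADER) - set(reader.fieldnames):
            raise PreconditionError(
                f"{path}: expected CSV header {_CSV_HEADER}")
        for i, row in enumerate(reader, start=2):
            try:
                temp = float(row["temperature_c"])
            except ValueError as exc:
                raise PreconditionError(f"{path}:{i}: bad temperature") from exc
            stage = row["stage"]
            if stage not in _STAGE_ATTR:
                raise PreconditionError(f"{path}:{i}: unknown stage {stage!r}")
            kind = "exit" if stage == "larva_to_exit" else "emergence"
            key = (row["id"], temp)
            rec = by_id.setdefault(key, DurationRecord(
                id=row["id"], temperature=temp, sex=row["sex"] or "unknown",
                fate=row["fate"] or "emerged", kind=kind))
            if row["duration_days"]:
                setattr(rec, _STAGE_ATTR[stage], float(row["duration_days"]))
    return list(by_id.values())
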