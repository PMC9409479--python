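"""Temperature-dependent development-rate models and thermal bioparameters.

Ten candidate models relate a constant rearing temperature T (degrees C) to the
development rate tau(T) (1/day, reciprocal of stage duration): two linear
estimators (ordinary least squares and the Ikemoto-Takai regression of D*T on
duration D) and eight nonlinear curves commonly used in insect thermal biology
(Logan-6, Briere-1/2, Lactin-1/2, an inverse second-order polynomial, a cubic
polynomial, and a simplified beta curve).

From fitted parameters the module extracts the thermal bioparameters that
drive phenology forecasting:

* ``LT``   lower temperature threshold (rate reaches zero from above), degC
* ``Topt`` temperature of maximal rate, degC
* ``UT``   upper (lethal) threshold, degC
* ``DD``   thermal constant in degree days (linear models only, 1/slope)

Traits without a closed form are located numerically: Topt by a coarse
0.1 degC grid scan refined by bounded minimisation, thresholds by bracketed
root finding on either side of Topt.  A trait whose defining root does not
exist in the search interval is reported as ``None``, never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .errors import PreconditionError

__all__ = [
    "RateModelSpec",
    "ThermalTraits",
    "MODEL_NAMES",
    "get_model",
    "evaluate_rate",
    "thermal_traits",
]

DEFAULT_SEARCH_INTERVAL = (0.0, 45.0)


@dataclass(frozen=True)
class RateModelSpec:
    """A named rate model: parameter list, fitting bounds, and the equation."""

    name: str
    param_names: tuple[str, ...]
    param_bounds: tuple[tuple[float, float], ...]
    _fn: Callable[..., np.ndarray] = field(repr=False)
    is_linear: bool = False

    def __post_init__(self):
        if len(self.param_names) != len(self.param_bounds):
            raise ValueError("param_names and param_bounds length mismatch")
        for lo, hi in self.param_bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{self.name}: bounds must be finite with low < high")

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __call__(self, params: Sequence[float], T) -> np.ndarray:
        return evaluate_rate(self, params, T)


@dataclass(frozen=True)
class ThermalTraits:
    """Thermal bioparameters of one stage; ``None`` marks an undefined trait."""

    LT: float | None = None
    Topt: float | None = None
    UT: float | None = None
    DD: float | None = None

    def __post_init__(self):
        if self.LT is not None and self.Topt is not None and self.UT is not None:
            if not (self.LT < self.Topt < self.UT):
                raise ValueError("thermal traits must satisfy LT < Topt < UT")
        if self.DD is not None and self.DD <= 0:
            raise ValueError("thermal constant DD must be positive")


# --- model equations ------------------------------------------------------
# Each takes (T, *params) with T an ndarray and returns the raw rate, which
# may be negative outside the viable temperature range.

def _ordinary_linear(T, a, b):
    return a * T + b


def _ikemoto(T, K, tmin):
    # Rate form of the D*T = K + Tmin*D regression line.
    return (T - tmin) / K


def _logan6(T, psi, rho, tmax, dt):
    return psi * (np.exp(rho * T) - np.exp(rho * tmax - (tmax - T) / dt))


def _briere1(T, a, tmin, tmax):
    tail = np.clip(tmax - T, 0.0, None)
    return a * T * (T - tmin) * np.sqrt(tail)


def _briere1_literal(T, a, tmin, tmax):
    return a * T * (T - tmin) * (tmax - T)


def _briere2(T, a, tmin, tmax, d):
    tail = np.clip(tmax - T, 0.0, None)
    return a * T * (T - tmin) * tail ** (1.0 / d)


def _lactin1(T, rho, tmax, dt):
    return np.exp(rho * T) - np.exp(rho * tmax - (tmax - T) / dt)


def _lactin2(T, rho, tmax, dt, lam):
    return _lactin1(T, rho, tmax, dt) + lam


def _inv_poly2(T, a, b, c):
    denom = 1.0 + b * T + c * T * T
    if np.any(np.abs(denom) < 1e-12):
        raise PreconditionError("inv_poly2 denominator is zero at a requested temperature")
    return a / denom


def _poly3(T, a, b, c, d):
    return ((a * T + b) * T + c) * T + d


def _beta_simplified(T, rho, alpha, beta):
    x = np.clip(T / 10.0, 0.0, None)
    return rho * (alpha - x) * x ** beta


_REGISTRY: dict[str, RateModelSpec] = {}


def _register(spec: RateModelSpec) -> RateModelSpec:
    _REGISTRY[spec.name] = spec
    return spec

ORDINARY_LINEAR = _register(RateModelSpec(
    "ordinary_linear", ("a", "b"), ((1e-5, 0.05), (-1.0, 0.5)),
    _ordinary_linear, is_linear=True))
IKEMOTO = _register(RateModelSpec(
    "ikemoto", ("K", "Tmin"), ((10.0, 2000.0), (0.0, 20.0)),
    _ikemoto, is_linear=True))
LOGAN6 = _register(RateModelSpec(
    "logan6", ("psi", "rho", "Tmax", "deltaT"),
    ((1e-5, 0.5), (0.01, 0.5), (28.0, 45.0), (0.5, 15.0)), _logan6))
BRIERE1 = _register(RateModelSpec(
    "briere1", ("a", "Tmin", "Tmax"),
    ((1e-8, 1e-3), (0.0, 14.0), (28.0, 45.0)), _briere1))
BRIERE2 = _register(RateModelSpec(
    "briere2", ("a", "Tmin", "Tmax", "d"),
    ((1e-8, 1e-3), (0.0, 14.0), (28.0, 45.0), (0.5, 10.0)), _briere2))
LACTIN1 = _register(RateModelSpec(
    "lactin1", ("rho", "Tmax", "deltaT"),
    ((1e-3, 0.3), (28.0, 45.0), (0.5, 20.0)), _lactin1))
LACTIN2 = _register(RateModelSpec(
    "lactin2", ("rho", "Tmax", "deltaT", "lambda"),
    ((1e-3, 0.3), (28.0, 45.0), (0.5, 20.0), (-2.0, 1.0)), _lactin2))
INV_POLY2 = _register(RateModelSpec(
    "inv_poly2", ("a", "b", "c"),
    ((-5.0, 5.0), (-2.0, 2.0), (-0.1, 0.1)), _inv_poly2))
POLY3 = _register(RateModelSpec(
    "poly3", ("a", "b", "c", "d"),
    ((-1e-3, 1e-3), (-0.05, 0.05), (-1.0, 1.0), (-5.0, 5.0)), _poly3))
BETA_SIMPLIFIED = _register(RateModelSpec(
    "beta_simplified", ("rho", "alpha", "beta"),
    ((1e-6, 10.0), (2.5, 6.0), (0.5, 12.0)), _beta_simplified))

# The literal Briere-1 without the square-root tail, kept for comparison with
# sources that typeset the curve without the exponent.  Not one of the ten
# candidates.
BRIERE1_LITERAL = RateModelSpec(
    "briere1_literal", ("a", "Tmin", "Tmax"),
    ((1e-8, 1e-2), (0.0, 14.0), (28.0, 45.0)), _briere1_literal)

MODEL_NAMES: tuple[str, ...] = tuple(_REGISTRY)

NONLINEAR_NAMES: tuple[str, ...] = tuple(
    n for n in MODEL_NAMES if not _REGISTRY[n].is_linear)


def get_model(name: str) -> RateModelSpec:
    """Look up a model by registry name; 'longan6' aliases 'logan6'."""
    key = name.lower()
    key = {"longan6": "logan6"}.get(key, key)
    if key == "briere1_literal":
        return BRIERE1_LITERAL
    try:
        return _REGISTRY[key]
    except KeyError:
        raise KeyError(
            f"unknown rate model {name!r}; choose from {sorted(_REGISTRY)}") from None


def evaluate_rate(spec: RateModelSpec | str, params: Sequence[float], T) -> np.ndarray:
    """Evaluate the raw model rate at temperature(s) T.

    Returns the equation value without clamping: negative rates outside the
    viable range are meaningful to threshold root-finding and are preserved.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.n_params,):
        raise PreconditionError(
            f"{spec.name} expects {spec.n_params} parameters "
            f"{spec.param_names}, got {params.shape}")
    T_arr = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T_arr)):
        raise PreconditionError("temperature must be finite")
    if spec.name in ("logan6", "lactin1", "lactin2") and params[spec.param_names.index("deltaT")] == 0:
        raise PreconditionError(f"{spec.name}: deltaT must be nonzero")
    out = spec._fn(T_arr, *params)
    return out if np.ndim(T) else float(out)


def _refine_root(f, lo: float, hi: float) -> float:
    return float(optimize.brentq(f, lo, hi, xtol=1e-9))


def _grid_argmax(f, interval: tuple[float, float]) -> float:
    lo, hi = interval
    grid = np.arange(lo, hi + 1e-9, 0.1)
    vals = f(grid)
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    if a == b:
        return float(grid[i])
    res = optimize.minimize_scalar(
        lambda t: -f(np.asarray(t)), bounds=(a, b), method="bounded",
        options={"xatol": 1e-6})
    return float(res.x)


def _bracketed_zero(f, lo: float, hi: float, step: float = 0.1) -> float | None:
    """First sign change scanning from lo to hi (either direction)."""
    if lo == hi:
        return None
    xs = np.arange(lo, hi, step if hi > lo else -step)
    xs = np.append(xs, hi)
    vals = f(xs)
    for x0, x1, v0, v1 in zip(xs[:-1], xs[1:], vals[:-1], vals[1:]):
        if v0 == 0.0:
            return float(x0)
        if np.sign(v0) != np.sign(v1):
            return _refine_root(f, min(x0, x1), max(x0, x1))
    return None


def thermal_traits(
    spec: RateModelSpec | str,
    params: Sequence[float],
    search_interval: tuple[float, float] = DEFAULT_SEARCH_INTERVAL,
) -> ThermalTraits:
    """Extract LT / Topt / UT / DD from fitted parameters.

    Linear models have closed forms (LT = -b/a and DD = 1/a for the ordinary
    line; LT = Tmin and DD = K for Ikemoto) and no Topt/UT.  Briere models
    carry LT and UT as parameters.  Everything else is numeric: Topt as the
    argmax over ``search_interval``; UT (LT) as the zero crossing above
    (below) Topt when the bracket contains a sign change.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    p = np.asarray(params, dtype=float)
    if p.shape != (spec.n_params,):
        raise PreconditionError(f"{spec.name} expects {spec.n_params} parameters")

    if spec.name == "ordinary_linear":
        a, b = p
        if a <= 0:  # no rise with temperature: thresholds are meaningless
            return ThermalTraits()
        return ThermalTraits(LT=-b / a, DD=1.0 / a)
    if spec.name == "ikemoto":
        K, tmin = p
        return ThermalTraits(LT=tmin, DD=K if K > 0 else None)

    def f(T):
        return evaluate_rate(spec, p, np.asarray(T, dtype=float))

    topt = _grid_argmax(f, search_interval)
    lo, hi = search_interval

    if spec.name in ("briere1", "briere2", "briere1_literal"):
        lt: float | None = float(p[1])
        ut: float | None = float(p[2])
    else:
        ut = _bracketed_zero(f, topt, hi)
        lt = _bracketed_zero(f, topt, lo)

    if f(np.asarray(topt)) <= 0:  # curve never positive: no meaningful optimum
        return ThermalTraits(LT=lt, UT=ut)
    return ThermalTraits(LT=lt, Topt=topt, UT=ut)
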