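"""Small-sample information-criterion ranking of rate-model fits.

Least-squares fits are compared with AIC computed from the residual sum of
squares, AIC = n ln(RSS/n) + 2p, and its small-sample correction
AICc = AIC + 2p(p+1)/(n - p - 1).  Akaike weights turn AICc differences into
relative model probabilities, w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2).

Pure AICc order can prefer a curve whose fitted upper threshold contradicts
rearing observations (larvae that stop developing at a known temperature);
:func:`rank_models` optionally flags such fits implausible and promotes the
best plausible candidate instead.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import rate_models
from .errors import PreconditionError
from .fitting import FitResult

__all__ = ["aic", "aicc", "akaike_weights", "rank_models", "ModelRanking",
           "RankedModel", "ranking_to_csv"]


def aic(n: int, p: int, rss: float) -> float:
    """Least-squares AIC.  RSS of zero yields -inf with a warning."""
    if n <= 0:
        raise PreconditionError("sample size must be positive")
    if rss < 0:
        raise PreconditionError("RSS cannot be negative")
    if rss == 0:
        warnings.warn("RSS is zero: AIC reported as -inf", RuntimeWarning,
                      stacklevel=2)
        return -math.inf
    return n * math.log(rss / n) + 2 * p


def aicc(n: int, p: int, rss: float) -> float:
    """Small-sample corrected AIC; requires n > p + 1."""
    if n - p - 1 <= 0:
        raise PreconditionError(
            f"AICc undefined for n <= p + 1 (small-sample correction "
            f"divides by n - p - 1 = {n - p - 1})")
    return aic(n, p, rss) + 2 * p * (p + 1) / (n - p - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Relative model probabilities from a set of AICc values."""
    vals = np.asarray(aicc_values, dtype=float)
    if vals.size == 0:
        raise PreconditionError("need at least one AICc value")
    if not np.all(np.isfinite(vals)):
        raise PreconditionError("AICc values must be finite")
    delta = vals - vals.min()
    rel = np.exp(-delta / 2.0)
    return rel / rel.sum()


@dataclass
class RankedModel:
    fit: FitResult
    aic: float
    aicc: float
    delta: float
    weight: float
    plausible: bool


@dataclass
class ModelRanking:
    """Fits sorted ascending by AICc (ties broken by model name)."""

    entries: list[RankedModel]
    best: str

    def __iter__(self):
        return iter(self.entries)

    def entry(self, model: str) -> RankedModel:
        for e in self.entries:
            if e.fit.model == model:
                return e
        raise KeyError(model)


def rank_models(
    fits: Sequence[FitResult],
    observed_failure_temp: float | None = None,
    margin: float = 1.0,
) -> ModelRanking:
    """Rank fits by AICc with an optional biological-plausibility screen.

    When ``observed_failure_temp`` is given, any model whose fitted upper
    threshold exceeds it by more than ``margin`` degC is flagged implausible
    and cannot be selected as best, mirroring the practice of rejecting an
    upper threshold above the temperature at which development was observed
    to fail.  ``best`` is the lowest-AICc plausible model (or the overall
    lowest when every model is flagged).
    """
    if not fits:
        raise PreconditionError("need at least one fit to rank")
    scored = []
    for f in fits:
        a = aic(f.n, f.p, f.rss)
        ac = aicc(f.n, f.p, f.rss)
        scored.append((f, a, ac))
    scored.sort(key=lambda t: (t[2], t[0].model))
    aiccs = [ac for _, _, ac in scored]
    if all(math.isfinite(ac) for ac in aiccs):
        weights = akaike_weights(aiccs)
    else:
        # Perfect fits (RSS = 0) carry -inf AICc: all weight goes to them.
        exact = [ac == -math.inf for ac in aiccs]
        weights = np.array([1.0 / sum(exact) if e else 0.0 for e in exact])
    best_aicc = scored[0][2]

    entries = []
    for (f, a, ac), w in zip(scored, weights):
        plausible = True
        if observed_failure_temp is not None:
            traits = f.traits
            if traits is None:
                traits = rate_models.thermal_traits(f.model, f.params) \
                    if f.model in rate_models.MODEL_NAMES else None
            ut = traits.UT if traits is not None else None
            if ut is not None and ut > observed_failure_temp + margin:
                plausible = False
        entries.append(RankedModel(f, a, ac, ac - best_aicc, float(w), plausible))

    best = next((e.fit.model for e in entries if e.plausible), entries[0].fit.model)
    return ModelRanking(entries, best)


def ranking_to_csv(ranking: ModelRanking, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["model", "n", "p", "rss", "adj_r2", "aic", "aicc",
                    "delta", "weight", "plausible", "params"])
        for e in ranking.entries:
            w.writerow([e.fit.model, e.fit.n, e.fit.p,
                        f"{e.fit.rss:.10g}", f"{e.fit.adj_r2:.6f}",
                        f"{e.aic:.4f}", f"{e.aicc:.4f}", f"{e.delta:.4f}",
                        f"{e.weight:.4f}", int(e.plausible),
                        ";".join(f"{v:.10g}" for v in e.fit.params)])
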