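"""Fitness (population growth rate) estimation from cell-count time series.

Fitness is the exponential growth rate g in N(t) = N(0) e^{g t}, estimated
either pointwise from successive counts, g_k = ln(N_{k+1}/N_k)/dt_k, or as
the OLS slope of ln N versus t.  For drug-exposure curves the pipeline
default restricts the linear fit to the last six time points to suppress
the transient immediately after drug addition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = ["GrowthCurve", "FitnessEstimate", "fitness_pointwise", "fitness_linear_fit", "r_squared"]


@dataclass
class GrowthCurve:
    """A (time, cell count) series grown at one (ATc, Zeocin) condition."""

    times: np.ndarray
    counts: np.ndarray
    condition: "Condition | None" = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape or self.times.size < 2:
            raise ValueError("need matching times/counts with >= 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts <= 0):
            raise ValueError("cell counts must be positive")


@dataclass(frozen=True)
class FitnessEstimate:
    """A growth-rate estimate with its standard error (both per hour)."""

    g: float
    stderr: float
    method: Literal["pointwise", "linear_fit"]
    n_points_used: int

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("standard error must be non-negative")


def fitness_pointwise(curve: GrowthCurve) -> FitnessEstimate:
    """Mean of per-interval growth rates ln(N_{k+1}/N_k)/dt_k, +/- SE."""
    g_k = np.diff(np.log(curve.counts)) / np.diff(curve.times)
    se = float(g_k.std(ddof=1) / math.sqrt(len(g_k))) if len(g_k) > 1 else 0.0
    return FitnessEstimate(g=float(g_k.mean()), stderr=se, method="pointwise",
                           n_points_used=len(curve.times))


def fitness_linear_fit(
    curve: GrowthCurve, drop_initial: int = 0, last_n: int | None = None
) -> FitnessEstimate:
    """OLS slope of ln N versus t over the retained points.

    ``drop_initial`` removes leading points; ``last_n`` keeps only the final
    n points (applied after dropping).  ``last_n=6`` is the pipeline default
    for Zeocin-exposure curves.
    """
    t = curve.times[drop_initial:]
    n = curve.counts[drop_initial:]
    if last_n is not None:
        t, n = t[-last_n:], n[-last_n:]
    if len(t) < 2:
        raise ValueError("fewer than 2 points retained for the linear fit")
    res = stats.linregress(t, np.log(n))
    se = 0.0 if len(t) == 2 else float(res.stderr)
    return FitnessEstimate(g=float(res.slope), stderr=se, method="linear_fit",
                           n_points_used=len(t))


def r_squared(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot about the observed mean.

    May be negative when the model underperforms the mean; reported as-is.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("predicted and observed must have equal length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot
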