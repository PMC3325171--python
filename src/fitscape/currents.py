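"""Cellular currents and nongenetic memory from stationary distributions.

Within a stationary fluorescence distribution cells keep moving: expression
drifts down by dilution as cells grow, and noise pushes cells back up.  The
*directional cellular current* through a threshold theta counts cells
crossing per unit time in one direction.  Because the reporter protein is
stable, the downward current is a pure dilution flux,

    I_down = theta * g(theta) * dN/dF |_{theta+},

with g(theta) the dilution (growth) rate of cells at the threshold.  When
instantaneous fitness varies with expression, stationarity forces a
compensating net upward current: cells produced in excess on the fitter
side must migrate across the threshold.  The mean residence times
(cellular memories) follow as tau_H = N_H / I_down and tau_L = N_L / I_up.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .cytometry import (
    DEFAULT_THRESHOLD,
    FluorescenceDistribution,
    bimodality_test,
    smooth_histogram,
)
from .fitness import ATcModelParams, Condition, gamma2

__all__ = [
    "CurrentEstimate",
    "MemoryEstimate",
    "kernel_smooth",
    "downward_current",
    "fitness_corrected_currents",
    "memory_from_currents",
    "memory_dose_response",
]


@dataclass(frozen=True)
class CurrentEstimate:
    """Directional currents (cells per hour) through a threshold."""

    theta: float
    i_down: float
    i_up: float
    n_low: float
    n_high: float

    def __post_init__(self) -> None:
        if self.i_down < 0 or self.i_up < 0:
            raise ValueError("currents must be non-negative")

    @property
    def net(self) -> float:
        """Net upward current I_up - I_down."""
        return self.i_up - self.i_down


@dataclass(frozen=True)
class MemoryEstimate:
    """Mean residence times (hours) of the low and high expression states.

    ``lower_bound_flag`` marks estimates where smoothing had to fill empty
    bins near the threshold, making tau_H a conservative lower bound.
    """

    tau_low: float
    tau_high: float
    theta: float
    condition: Condition | None = None
    lower_bound_flag: bool = False

    def __post_init__(self) -> None:
        if self.tau_low < 0 or self.tau_high < 0:
            raise ValueError("memories must be non-negative")


def kernel_smooth(dist: FluorescenceDistribution, bandwidth_bins: float = 2.0) -> FluorescenceDistribution:
    """Gaussian-kernel smoothing over bins (used to fill empty bins)."""
    smoothed = gaussian_filter1d(dist.counts.astype(float), sigma=bandwidth_bins, mode="nearest")
    return FluorescenceDistribution(
        bin_edges=dist.bin_edges,
        counts=dist.counts,
        smoothed_counts=smoothed,
        smooth_window=dist.smooth_window or 32,
        n_dropped=dist.n_dropped,
    )


def _density_above(dist: FluorescenceDistribution, theta: float) -> tuple[float, bool]:
    """Smoothed density dN/dF (events per a.u.) immediately above theta.

    Returns the density of the first bin above the one containing theta and
    a flag marking whether the raw bin there was empty (smoothing filled it).
    """
    idx = dist.bin_index(theta)
    above = idx + 1
    if above >= dist.n_bins:
        raise ValueError("threshold sits at the histogram edge")
    if dist.smoothed_counts is None:
        raise ValueError("distribution must be smoothed before current estimation")
    dens = dist.smoothed_counts[above] / dist.bin_widths[above]
    return float(dens), bool(dist.counts[above] == 0)


def downward_current(
    dist: FluorescenceDistribution,
    theta: float,
    condition: Condition,
    atc_params: ATcModelParams = ATcModelParams(),
    g0: float | None = None,
) -> float:
    """Dilution flux of cells crossing theta downward (cells per hour).

    I_down = theta * g0 * gamma2(theta, C) * dN/dF at theta+.  The dilution
    rate uses the rtTA-cost marginal gamma2 only, matching the Zeocin-free
    context in which stationary distributions are measured.
    """
    if g0 is None:
        g0 = atc_params.g0
    dens, _ = _density_above(dist, theta)
    g_theta = g0 * gamma2(theta, condition.atc_ng_ml, atc_params)
    return float(theta * g_theta * dens)


def fitness_corrected_currents(
    dist: FluorescenceDistribution,
    theta: float,
    fitness_fn: Callable[[np.ndarray], np.ndarray],
    g_t: float,
    condition: Condition,
    atc_params: ATcModelParams = ATcModelParams(),
    g0: float | None = None,
    stationarity_tol: float = 1e-3,
) -> CurrentEstimate:
    """Both directional currents, corrected for fitness differences.

    In a stationary distribution the net upward current through theta must
    equal the surplus cell production below it,

        net = N_tot * integral_{F < theta} (g(F) - g_T) p(F) dF,

    evaluated by trapezoidal quadrature over bin centres; then
    I_up = I_down + net.  A warning is raised if the full-range integral
    (which must vanish when g_T is the p-weighted mean fitness) exceeds
    ``stationarity_tol`` relative to N_tot * |g_T|.
    """
    if dist.smoothed_counts is None:
        raise ValueError("distribution must be smoothed before current estimation")
    centers = dist.bin_centers
    mass = dist.probability(smoothed=True)
    dens = mass / dist.bin_widths  # probability density per a.u.
    n_tot = float(dist.smoothed_counts.sum())
    g_vals = np.asarray(fitness_fn(centers), dtype=float)

    full = float(np.trapezoid((g_vals - g_t) * dens, centers))
    if abs(full) > stationarity_tol * max(abs(g_t), 1e-12):
        warnings.warn(
            f"stationarity violated: full-range net flux {full:.3g} per hour",
            stacklevel=2,
        )
    low = centers < theta
    net = n_tot * float(np.trapezoid((g_vals[low] - g_t) * dens[low], centers[low]))
    i_down = downward_current(dist, theta, condition, atc_params, g0)
    i_up = i_down + net
    if i_up < 0:
        warnings.warn("net downward flux exceeds the dilution current; clamping I_up to 0",
                      stacklevel=2)
        i_up = 0.0
    n_high = float(dist.smoothed_counts[centers >= theta].sum())
    return CurrentEstimate(theta=theta, i_down=i_down, i_up=i_up,
                           n_low=n_tot - n_high, n_high=n_high)


def memory_from_currents(
    dist: FluorescenceDistribution,
    estimate: CurrentEstimate,
    condition: Condition | None = None,
) -> MemoryEstimate:
    """Residence times tau_H = N_H / I_down and tau_L = N_L / I_up.

    A zero current yields infinite memory (flagged through the value, not
    an exception).
    """
    tau_high = math.inf if estimate.i_down == 0 else estimate.n_high / estimate.i_down
    tau_low = math.inf if estimate.i_up == 0 else estimate.n_low / estimate.i_up
    _, filled = _density_above(dist, estimate.theta)
    return MemoryEstimate(
        tau_low=tau_low,
        tau_high=tau_high,
        theta=estimate.theta,
        condition=condition,
        lower_bound_flag=filled,
    )


def _auto_threshold(dist: FluorescenceDistribution) -> float:
    """Bimodality-test threshold, or the constant fallback if unimodal."""
    res = bimodality_test(dist)
    if res.is_bimodal and res.selected_threshold is not None:
        return res.selected_threshold
    return DEFAULT_THRESHOLD


def memory_dose_response(
    dists: Mapping[float, FluorescenceDistribution],
    atc_params: ATcModelParams = ATcModelParams(),
    g0: float | None = None,
    theta: float | None = None,
    smooth_window: int = 32,
) -> pd.DataFrame:
    """Memory curves tau_L(C), tau_H(C) across inducer concentrations.

    ``dists`` maps each ATc level (ng/ml) to its stationary Zeocin-free
    distribution.  Each distribution is moving-average smoothed (if not
    already), thresholded by the bimodality test (constant fallback when
    unimodal, or ``theta`` if given), and processed through the
    fitness-corrected current estimator with g(F) = g0 * gamma2(F, C).

    Returns a DataFrame with one row per condition: atc_ng_ml, theta,
    i_down, i_up, tau_low, tau_high, lower_bound.
    """
    if g0 is None:
        g0 = atc_params.g0
    rows = []
    for c in sorted(dists):
        d = dists[c]
        if d.smoothed_counts is None:
            d = smooth_histogram(d, smooth_window)
        th = theta if theta is not None else _auto_threshold(d)
        cond = Condition(atc_ng_ml=c, zeocin_mg_ml=0.0)
        g_fn = lambda fc, _c=c: g0 * np.asarray(gamma2(fc, _c, atc_params))
        # trapezoid-consistent weighted mean so the full-range net flux
        # vanishes identically under the same quadrature as the currents
        centers = d.bin_centers
        dens = d.probability(smoothed=True) / d.bin_widths
        g_t = float(
            np.trapezoid(g_fn(centers) * dens, centers) / np.trapezoid(dens, centers)
        )
        est = fitness_corrected_currents(d, th, g_fn, g_t, cond, atc_params, g0)
        mem = memory_from_currents(d, est, cond)
        rows.append(
            {
                "atc_ng_ml": c,
                "theta": th,
                "i_down": est.i_down,
                "i_up": est.i_up,
                "tau_low": mem.tau_low,
                "tau_high": mem.tau_high,
                "lower_bound": mem.lower_bound_flag,
            }
        )
    return pd.DataFrame(rows)
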