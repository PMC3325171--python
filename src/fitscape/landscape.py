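"""Two-dimensional fitness landscapes over (ATc, Zeocin) and their analysis.

Two predictors of overall population fitness are compared across the
inducer x antibiotic plane:

* *fast switching*: the distribution-weighted average of the Bliss product
  of marginal fitness reductions, assuming phenotype switching is much
  faster than division so the Zeocin-free distribution p(F) persists;
* *memory aware*: per inducer level, the cellular-memory estimates set the
  switching rates (r = 1/tau_L, f = 1/tau_H) and the marginal fitness
  functions set state-level division rates at the representative low/high
  fluorescences; fitness is the dominant eigenvalue of the two-state model.

With a long-lived protected state the memory-aware surface exceeds the
fast-switching one under antibiotic, peaking at the lowest inducer level
that populates the high state at all -- the drug-resistance "sweet spot".
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cytometry import (
    DEFAULT_THRESHOLD,
    FluorescenceDistribution,
    bimodality_test,
    smooth_histogram,
    subpopulation_means_from_distribution,
)
from .fitness import (
    ATcModelParams,
    Condition,
    ZeocinModelParams,
    gamma_joint,
    overall_fitness_fast_switching,
)
from .growth import r_squared
from .twostate import TwoStateParams, population_fitness, solve_two_state

__all__ = [
    "FitnessSurface",
    "SweetSpot",
    "SelectionOutcome",
    "two_state_params_for",
    "predict_surface",
    "find_sweet_spot",
    "compare_models",
    "selection_reshaping",
    "DEFAULT_ATC_GRID",
    "DEFAULT_ZEOCIN_GRID",
]

DEFAULT_ATC_GRID = tuple(np.arange(0.0, 20.0 + 1e-9, 0.25))
DEFAULT_ZEOCIN_GRID = tuple(np.arange(0.0, 4.0 + 1e-9, 0.25))


@dataclass
class FitnessSurface:
    """Predicted fitness g_T (per hour) on an (ATc, Zeocin) grid.

    ``values[i, j]`` is the prediction at ``atc_grid[i]``, ``zeocin_grid[j]``.
    ``provenance`` hashes the inputs so identical inputs yield identical
    surfaces byte-for-byte.
    """

    atc_grid: np.ndarray
    zeocin_grid: np.ndarray
    values: np.ndarray
    mode: str
    provenance: str = ""

    def __post_init__(self) -> None:
        self.atc_grid = np.asarray(self.atc_grid, dtype=float)
        self.zeocin_grid = np.asarray(self.zeocin_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.atc_grid) <= 0) or np.any(np.diff(self.zeocin_grid) <= 0):
            raise ValueError("grids must be sorted ascending")
        if self.values.shape != (self.atc_grid.size, self.zeocin_grid.size):
            raise ValueError("values shape must be (len(atc_grid), len(zeocin_grid))")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("surface values must be finite")

    def slice_at_zeocin(self, z: float) -> np.ndarray:
        j = np.flatnonzero(np.isclose(self.zeocin_grid, z))
        if j.size == 0:
            raise ValueError(f"Zeocin level {z} not on the grid")
        return self.values[:, j[0]]

    def to_frame(self) -> pd.DataFrame:
        cc, zz = np.meshgrid(self.atc_grid, self.zeocin_grid, indexing="ij")
        return pd.DataFrame(
            {
                "atc_ng_ml": cc.ravel(),
                "zeocin_mg_ml": zz.ravel(),
                "g_per_h": self.values.ravel(),
                "mode": self.mode,
            }
        )


@dataclass(frozen=True)
class SweetSpot:
    """Fitness optimum along the inducer axis at fixed antibiotic."""

    condition: Condition
    g_t: float
    sharpness: float  # negative second difference along ATc at the optimum
    flat: bool = False
    on_boundary: bool = False


def _interp_memory(memory: pd.DataFrame, atc: float) -> tuple[float, float]:
    """Memory at an inducer level, log-linearly interpolated if absent."""
    cs = memory["atc_ng_ml"].to_numpy()
    hit = np.flatnonzero(np.isclose(cs, atc))
    if hit.size:
        row = memory.iloc[hit[0]]
        return float(row["tau_low"]), float(row["tau_high"])
    warnings.warn(f"no memory estimate at ATc = {atc}; interpolating log-linearly",
                  stacklevel=2)
    taus = []
    for col in ("tau_low", "tau_high"):
        taus.append(float(np.exp(np.interp(atc, cs, np.log(memory[col].to_numpy())))))
    return taus[0], taus[1]


def two_state_params_for(
    dist: FluorescenceDistribution,
    tau_low: float,
    tau_high: float,
    atc_ng_ml: float,
    zeocin_mg_ml: float,
    zeocin_params: ZeocinModelParams = ZeocinModelParams(),
    atc_params: ATcModelParams = ATcModelParams(),
    g0: float | None = None,
    theta: float | None = None,
) -> TwoStateParams:
    """Memory-aware two-state parameterisation at one condition.

    Switching rates are the reciprocal memories; division rates are
    g0 * gamma(F_bar, C, Z) evaluated at the representative (histogram
    count-weighted) fluorescences of the low and high subpopulations of
    the Zeocin-free distribution.
    """
    if g0 is None:
        g0 = atc_params.g0
    if dist.smoothed_counts is None:
        dist = smooth_histogram(dist)
    if theta is None:
        res = bimodality_test(dist)
        theta = res.selected_threshold if res.is_bimodal else DEFAULT_THRESHOLD
    f_low, f_high = subpopulation_means_from_distribution(dist, theta)
    cond = Condition(atc_ng_ml=atc_ng_ml, zeocin_mg_ml=zeocin_mg_ml)
    g_low = g0 * float(gamma_joint(f_low, cond, zeocin_params, atc_params))
    g_high = g0 * float(gamma_joint(f_high, cond, zeocin_params, atc_params))
    r = 0.0 if math.isinf(tau_low) else 1.0 / tau_low
    f = 0.0 if math.isinf(tau_high) else 1.0 / tau_high
    return TwoStateParams(r=r, f=f, g_low=g_low, g_high=g_high)


def _provenance(*parts) -> str:
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, np.ndarray):
            h.update(np.ascontiguousarray(part).tobytes())
        else:
            h.update(repr(part).encode())
    return h.hexdigest()[:16]


def predict_surface(
    dists: Mapping[float, FluorescenceDistribution],
    memory: pd.DataFrame | None,
    zeocin_params: ZeocinModelParams = ZeocinModelParams(),
    atc_params: ATcModelParams = ATcModelParams(),
    g0: float | None = None,
    atc_grid: Sequence[float] | None = None,
    zeocin_grid: Sequence[float] = DEFAULT_ZEOCIN_GRID,
    mode: str = "memory_aware",
) -> FitnessSurface:
    """Predict the overall-fitness surface over (ATc, Zeocin).

    ``dists`` are the stationary Zeocin-free fluorescence distributions per
    inducer level; they parameterise the expression structure at every
    antibiotic level (selection acts only through the fitness functions).
    ``memory`` (required for memory_aware mode) is the output of
    ``memory_dose_response``.
    """
    if mode not in ("fast_switching", "memory_aware"):
        raise ValueError("mode must be 'fast_switching' or 'memory_aware'")
    if g0 is None:
        g0 = atc_params.g0
    if atc_grid is None:
        atc_grid = sorted(dists)
    atc_grid = np.asarray(list(atc_grid), dtype=float)
    zeocin_grid = np.asarray(list(zeocin_grid), dtype=float)
    missing = [c for c in atc_grid if c not in dists]
    if missing:
        raise ValueError(f"no fluorescence distribution for ATc levels {missing}")
    if mode == "memory_aware" and memory is None:
        raise ValueError("memory_aware mode requires a memory table")

    values = np.empty((atc_grid.size, zeocin_grid.size))
    for i, c in enumerate(atc_grid):
        dist = dists[c]
        if dist.smoothed_counts is None:
            dist = smooth_histogram(dist)
        if mode == "fast_switching":
            for j, z in enumerate(zeocin_grid):
                values[i, j] = overall_fitness_fast_switching(
                    dist, Condition(c, z), zeocin_params, atc_params, g0
                )
        else:
            tau_low, tau_high = _interp_memory(memory, c)
            for j, z in enumerate(zeocin_grid):
                params = two_state_params_for(
                    dist, tau_low, tau_high, c, z, zeocin_params, atc_params, g0
                )
                values[i, j] = population_fitness(params)
    prov = _provenance(
        mode, atc_grid, zeocin_grid, g0, zeocin_params, atc_params,
        *[dists[c].counts for c in atc_grid],
        memory.to_csv(index=False) if memory is not None else None,
    )
    return FitnessSurface(atc_grid, zeocin_grid, values, mode, prov)


def find_sweet_spot(surface: FitnessSurface, z_slice: float, flat_tol: float = 1e-9) -> SweetSpot:
    """Locate the fitness optimum along ATc at a fixed Zeocin level.

    Sharpness is the negative discrete second difference of g_T along the
    inducer axis at the optimum (one-sided at grid boundaries).  A flat
    slice reports the boundary with the flat flag set.
    """
    g = surface.slice_at_zeocin(z_slice)
    flat = bool(g.max() - g.min() <= flat_tol)
    i = int(np.argmax(g))
    boundary = i in (0, len(g) - 1)
    if len(g) >= 3:
        k = min(max(i, 1), len(g) - 2)
        sharp = float(-(g[k - 1] - 2.0 * g[k] + g[k + 1]))
    else:
        sharp = 0.0
    return SweetSpot(
        condition=Condition(atc_ng_ml=float(surface.atc_grid[i]), zeocin_mg_ml=z_slice),
        g_t=float(g[i]),
        sharpness=sharp,
        flat=flat,
        on_boundary=boundary,
    )


def compare_models(
    surface_mem: FitnessSurface,
    surface_fast: FitnessSurface,
    observed: Sequence[float],
    z_slice: float,
) -> tuple[float, float]:
    """R-squared of both predictors against observed fitness along ATc.

    ``observed`` must align with the shared ATc grid of both surfaces at
    the given Zeocin level.  Returns (R2_memory, R2_fast).
    """
    if not np.array_equal(surface_mem.atc_grid, surface_fast.atc_grid):
        raise ValueError("surfaces must share the ATc grid")
    obs = np.asarray(observed, dtype=float)
    return (
        r_squared(surface_mem.slice_at_zeocin(z_slice), obs),
        r_squared(surface_fast.slice_at_zeocin(z_slice), obs),
    )


@dataclass(frozen=True)
class SelectionOutcome:
    """Reshaping of the subpopulation structure under selection."""

    fraction_high_before: float
    fraction_high_after: float

    @property
    def fold_change(self) -> float:
        if self.fraction_high_before == 0:
            return math.inf
        return self.fraction_high_after / self.fraction_high_before


def selection_reshaping(
    dist_before: FluorescenceDistribution,
    params: TwoStateParams,
    duration: float,
    theta: float = DEFAULT_THRESHOLD,
) -> SelectionOutcome:
    """Evolve the low/high split under the two-state model for ``duration``.

    The initial composition is the histogram mass on either side of
    ``theta``; the expected composition after ``duration`` hours follows the
    closed-form solution.  Reports the high-expressor fraction before and
    after and (via ``fold_change``) its amplification by selection.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    mass = dist_before.probability()
    high0 = float(mass[dist_before.bin_centers >= theta].sum())
    n = solve_two_state(params).propagate([1.0 - high0, high0], float(duration))
    return SelectionOutcome(fraction_high_before=high0,
                            fraction_high_after=float(n[1] / n.sum()))
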