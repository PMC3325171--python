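"""Instantaneous and population-level fitness models.

Two semi-phenomenological marginal fitness-reduction functions describe how
a single cell's division rate depends on its fluorescence F (a proxy for
the yEGFP::ZeoR resistance-protein level) and the environment:

* ``gamma1(F, Z)`` -- Zeocin toxicity.  Extracellular Zeocin at concentration
  Z diffuses freely across the membrane (exchange rate h_Z), binds
  irreversibly to unbound ZeoR (rate s), and bound complexes turn over at
  the ZeoR dilution/degradation rate d.  The steady-state intracellular
  free Zeocin Z_i damages DNA, which is repaired at a constant rate, giving
  the saturable reduction gamma1 = 1 / (1 + chi * Z_i^phi).

* ``gamma2(F, C)`` -- cost of active rtTA.  ATc at concentration C activates
  rtTA with saturable binding (scale beta); the toxicity of active rtTA is
  proportional to expression, so gamma2 = 1 / (1 + alpha * (F/F_ref) * C/(beta + C)).

Their Bliss product gamma = gamma1 * gamma2 combines the two independent
stresses, and the fast-switching predictor averages g0 * gamma over the
measured fluorescence distribution p(F).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .cytometry import FluorescenceDistribution
from .growth import FitnessEstimate, GrowthCurve, fitness_linear_fit

__all__ = [
    "Condition",
    "ZeocinModelParams",
    "ATcModelParams",
    "IntracellularState",
    "intracellular_zeocin",
    "gamma1",
    "gamma2",
    "gamma_joint",
    "overall_fitness_fast_switching",
    "fit_zeocin_params",
    "fit_atc_params",
    "DEFAULT_G0",
]

#: Default maximal fitness g0 (per hour, division rate at ATc = 0, Zeocin = 0).
DEFAULT_G0 = 0.35


@dataclass(frozen=True)
class Condition:
    """An environment: ATc inducer (ng/ml) and extracellular Zeocin (mg/ml)."""

    atc_ng_ml: float = 0.0
    zeocin_mg_ml: float = 0.0

    def __post_init__(self) -> None:
        if self.atc_ng_ml < 0 or self.zeocin_mg_ml < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class ZeocinModelParams:
    """Parameters of the intracellular-Zeocin toxicity model.

    ``phi``, ``chi`` and ``s`` are fit to marginal Zeocin dose-response
    fitness data; the membrane exchange rate ``h_z`` and ZeoR turnover ``d``
    are held fixed.  ``zeocin_scale`` and ``fluorescence_scale`` convert the
    instrument units (mg/ml, fluorescence a.u.) into the concentration units
    of the mass-action model; they are calibration constants of the package,
    chosen once so that the default parameter set spans a protective/toxic
    dynamic range over Z in [0, 4] mg/ml and F in [1, 1e4] a.u.
    """

    phi: float = 1.182
    chi: float = 0.5028e-7
    s: float = 1.2732e6
    h_z: float = 0.5
    d: float = 0.25
    zeocin_scale: float = 5.0e6
    fluorescence_scale: float = 1.0e5

    def __post_init__(self) -> None:
        for name in ("phi", "chi", "s", "h_z", "d", "zeocin_scale", "fluorescence_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ATcModelParams:
    """Parameters of the active-rtTA toxicity model.

    ``alpha`` scales the toxicity of ATc-activated rtTA, ``beta`` (ng/ml) is
    the saturable ATc binding scale, and ``g0`` (per hour) the maximal
    fitness at the origin condition.  ``f_ref`` (a.u.) normalises
    fluorescence inside gamma2 so that alpha is scale-free.
    """

    alpha: float = 936.0
    beta: float = 5.8
    g0: float = DEFAULT_G0
    f_ref: float = 3.0e5

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.g0 <= 0:
            raise ValueError("g0 must be positive")
        if self.f_ref <= 0:
            raise ValueError("f_ref must be positive")


@dataclass(frozen=True)
class IntracellularState:
    """Steady-state intracellular species, in model concentration units.

    ``total`` is the total ZeoR pool (unbound + bound), i.e. the fluorescence
    mapped into model units; ``unbound + bound == total`` holds exactly.
    """

    z_internal: np.ndarray | float
    unbound: np.ndarray | float
    bound: np.ndarray | float

    @property
    def total(self) -> np.ndarray | float:
        return self.unbound + self.bound


def intracellular_zeocin(
    fluorescence: np.ndarray | float,
    zeocin_mg_ml: np.ndarray | float,
    params: ZeocinModelParams = ZeocinModelParams(),
) -> IntracellularState:
    """Steady-state free intracellular Zeocin for given F (a.u.) and Z (mg/ml).

    Solves the balance   h_Z (Z - Z_i) = s Z_i R_u,   B = s Z_i R_u / d,
    F = R_u + B  (all in model units).  Eliminating R_u = F / (1 + s Z_i/d)
    turns the balance into a quadratic in Z_i with a single root in [0, Z],
    evaluated here in a cancellation-free form.
    """
    f_au = np.asarray(fluorescence, dtype=float)
    z_mg = np.asarray(zeocin_mg_ml, dtype=float)
    if np.any(f_au < 0) or np.any(z_mg < 0):
        raise ValueError("fluorescence and Zeocin must be non-negative")
    h, s, d = params.h_z, params.s, params.d
    f_m = params.fluorescence_scale * f_au
    z_m = params.zeocin_scale * z_mg

    # quadratic A Z_i^2 + B Z_i + C = 0 with A = h s/d, C = -h Z; pick the
    # cancellation-free form of the positive root for either sign of B
    # (B >= 0: strong binding sink; B < 0: sink saturated, Z_i near Z).
    a_coef = h * s / d if d > 0 else np.inf
    b_coef = h + s * f_m - a_coef * z_m
    with np.errstate(over="ignore"):
        disc = np.sqrt(b_coef * b_coef + 4.0 * a_coef * h * z_m)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_i = np.where(
            b_coef >= 0,
            2.0 * h * z_m / (b_coef + disc),
            np.where(a_coef > 0, (disc - b_coef) / (2.0 * a_coef), z_m),
        )
        z_i = np.where(z_m > 0, z_i, 0.0)
        unbound = np.where(
            f_m > 0, f_m / (1.0 + s * z_i / d if d > 0 else np.inf), 0.0
        )
    bound = f_m - unbound
    if np.ndim(fluorescence) == 0 and np.ndim(zeocin_mg_ml) == 0:
        return IntracellularState(float(z_i), float(unbound), float(bound))
    return IntracellularState(z_i, unbound, bound)


def gamma1(
    fluorescence: np.ndarray | float,
    zeocin_mg_ml: np.ndarray | float,
    params: ZeocinModelParams = ZeocinModelParams(),
) -> np.ndarray | float:
    """Marginal fitness reduction from Zeocin: 1 / (1 + chi * Z_i^phi)."""
    state = intracellular_zeocin(fluorescence, zeocin_mg_ml, params)
    z_i = np.asarray(state.z_internal, dtype=float)
    out = 1.0 / (1.0 + params.chi * np.power(z_i, params.phi))
    return float(out) if np.ndim(fluorescence) == 0 and np.ndim(zeocin_mg_ml) == 0 else out


def gamma2(
    fluorescence: np.ndarray | float,
    atc_ng_ml: np.ndarray | float,
    params: ATcModelParams = ATcModelParams(),
) -> np.ndarray | float:
    """Marginal fitness reduction from active rtTA.

    gamma2 = 1 / (1 + alpha * (F / F_ref) * C / (beta + C)); equals 1 at C = 0
    and saturates to 1 / (1 + alpha F / F_ref) as C -> infinity.
    """
    f_au = np.asarray(fluorescence, dtype=float)
    c = np.asarray(atc_ng_ml, dtype=float)
    if np.any(f_au < 0) or np.any(c < 0):
        raise ValueError("fluorescence and ATc must be non-negative")
    occ = np.divide(c, params.beta + c, out=np.zeros_like(c, dtype=float), where=(params.beta + c) > 0)
    out = 1.0 / (1.0 + params.alpha * (f_au / params.f_ref) * occ)
    return float(out) if np.ndim(fluorescence) == 0 and np.ndim(atc_ng_ml) == 0 else out


def gamma_joint(
    fluorescence: np.ndarray | float,
    condition: Condition,
    zeocin_params: ZeocinModelParams = ZeocinModelParams(),
    atc_params: ATcModelParams = ATcModelParams(),
) -> np.ndarray | float:
    """Bliss-independent joint reduction gamma = gamma1(F, Z) * gamma2(F, C)."""
    return gamma1(fluorescence, condition.zeocin_mg_ml, zeocin_params) * gamma2(
        fluorescence, condition.atc_ng_ml, atc_params
    )


def overall_fitness_fast_switching(
    dist: FluorescenceDistribution,
    condition: Condition,
    zeocin_params: ZeocinModelParams = ZeocinModelParams(),
    atc_params: ATcModelParams = ATcModelParams(),
    g0: float | None = None,
) -> float:
    """Distribution-averaged population fitness, fast-switching limit.

    g_T = g0 * sum_bins gamma(F_bin, C, Z) * p(F_bin), with bin-centre
    fluorescences and the normalised probability mass p.  Assumes switching
    is much faster than division, so p(F) is unchanged by selection.
    """
    if g0 is None:
        g0 = atc_params.g0
    p = dist.probability()
    total = p.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"distribution is not normalised (sum p = {total})")
    g = gamma_joint(dist.bin_centers, condition, zeocin_params, atc_params)
    return float(g0 * np.sum(g * p))


# ---------------------------------------------------------------------------
# Marginal-curve fitting
# ---------------------------------------------------------------------------


def _measure_marginal_fitness(curves: Sequence[GrowthCurve], last_n: int | None) -> np.ndarray:
    ests = [fitness_linear_fit(c, last_n=last_n) for c in curves]
    return np.array([e.g for e in ests])


def fit_zeocin_params(
    curves: Sequence[GrowthCurve],
    dist_at_zero_atc: FluorescenceDistribution,
    *,
    base: ZeocinModelParams = ZeocinModelParams(),
    last_n: int | None = 6,
) -> tuple[ZeocinModelParams, float]:
    """Fit (phi, chi, s) and g0 to a Zeocin dose-response at ATc = 0.

    Each growth curve carries its Zeocin concentration; measured fitness per
    level comes from the OLS slope of ln N over the last ``last_n`` points.
    Predictions use the fast-switching average of gamma1 over the ATc = 0
    fluorescence distribution.  Nelder-Mead in (log10 phi, log10 chi,
    log10 s, g0) from multiple starts; h_Z and d stay fixed.

    Returns ``(fitted_params, g0)``.
    """
    z_levels = np.array([c.condition.zeocin_mg_ml for c in curves])
    if len(z_levels) < 4 or 0.0 not in z_levels:
        raise ValueError("need >= 4 Zeocin levels including Z = 0")
    if any(c.condition.atc_ng_ml != 0 for c in curves):
        raise ValueError("Zeocin marginal fit expects ATc = 0 curves")
    g_obs = _measure_marginal_fitness(curves, last_n)
    p = dist_at_zero_atc.probability()
    f_centers = dist_at_zero_atc.bin_centers
    g0_init = float(g_obs[np.argmin(z_levels)])

    def predict(params: ZeocinModelParams, g0: float) -> np.ndarray:
        gam = np.array([np.sum(gamma1(f_centers, z, params) * p) for z in z_levels])
        return g0 * gam

    def objective(x: np.ndarray) -> float:
        phi, chi, s = 10.0 ** x[0], 10.0 ** x[1], 10.0 ** x[2]
        g0 = x[3]
        if g0 <= 0 or not np.all(np.isfinite(x)):
            return 1e12
        params = replace(base, phi=phi, chi=chi, s=s)
        pred = predict(params, g0)
        if not np.all(np.isfinite(pred)):
            return 1e12
        return float(np.sum((pred - g_obs) ** 2))

    x_base = np.array([math.log10(base.phi), math.log10(base.chi), math.log10(base.s), g0_init])
    starts = [
        x_base,
        x_base + np.array([-0.3, -0.5, 0.5, 0.0]),
        x_base + np.array([0.3, 0.5, -0.5, 0.0]),
        x_base + np.array([-0.3, 0.5, 0.5, 0.0]),
        x_base + np.array([0.3, -0.5, -0.5, 0.0]),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-14, "maxiter": 6000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"Zeocin marginal fit did not converge: {best}")
    fitted = replace(base, phi=10.0 ** best.x[0], chi=10.0 ** best.x[1], s=10.0 ** best.x[2])
    return fitted, float(best.x[3])


def fit_atc_params(
    curves: Sequence[GrowthCurve],
    dists: dict[float, FluorescenceDistribution],
    *,
    base: ATcModelParams = ATcModelParams(),
    last_n: int | None = None,
) -> ATcModelParams:
    """Fit (alpha, beta, g0) to an ATc dose-response at Zeocin = 0.

    ``dists`` maps each ATc level to its stationary Zeocin-free fluorescence
    distribution.  Same fitting contract as the Zeocin marginal fit.
    """
    c_levels = np.array([c.condition.atc_ng_ml for c in curves])
    if len(c_levels) < 4 or 0.0 not in c_levels:
        raise ValueError("need >= 4 ATc levels including C = 0")
    if any(c.condition.zeocin_mg_ml != 0 for c in curves):
        raise ValueError("ATc marginal fit expects Zeocin = 0 curves")
    missing = [c for c in c_levels if c not in dists]
    if missing:
        raise ValueError(f"missing fluorescence distributions for ATc levels {missing}")
    g_obs = _measure_marginal_fitness(curves, last_n)
    g0_init = float(g_obs[np.argmin(c_levels)])

    def objective(x: np.ndarray) -> float:
        alpha, beta, g0 = 10.0 ** x[0], 10.0 ** x[1], x[2]
        if g0 <= 0 or not np.all(np.isfinite(x)):
            return 1e12
        params = replace(base, alpha=alpha, beta=beta, g0=g0)
        sse = 0.0
        for c, g_e in zip(c_levels, g_obs):
            d = dists[c]
            pred = g0 * np.sum(gamma2(d.bin_centers, c, params) * d.probability())
            sse += (pred - g_e) ** 2
        return float(sse)

    x_base = np.array([math.log10(base.alpha), math.log10(base.beta), g0_init])
    starts = [x_base] + [
        x_base + np.array([da, db, 0.0]) for da in (-0.7, 0.7) for db in (-0.5, 0.5)
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-14, "maxiter": 6000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"ATc marginal fit did not converge: {best}")
    return replace(base, alpha=10.0 ** best.x[0], beta=10.0 ** best.x[1], g0=float(best.x[2]))
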