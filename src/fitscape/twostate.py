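"""Two-state population dynamics of low/high expressor subpopulations.

The population is partitioned into cells below (L) and above (H) a
fluorescence threshold.  L cells divide at rate ``g_L`` and rise into H at
rate ``r``; H cells divide at rate ``g_H`` and fall back at rate ``f``.  The
expected subpopulation sizes ``(N_L, N_H)`` then obey the linear system

    d/dt [N_L, N_H] = A [N_L, N_H],   A = [[g_L - r, f], [r, g_H - f]]

whose dominant eigenvalue ``a_1`` is the asymptotic exponential growth rate
(overall population fitness).  This module provides the spectral solution,
switching-rate fitting from cell-sorting relaxation experiments, lineage
occupancy statistics, and piecewise integration through fluctuating
environments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Literal, Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "TwoStateParams",
    "SpectralSolution",
    "SortRelaxationData",
    "SwitchingRateFit",
    "EnvironmentSchedule",
    "solve_two_state",
    "population_fitness",
    "normalize_log_ratios",
    "fit_switching_rates",
    "lineage_occupancy",
    "rates_from_memory",
    "simulate_fluctuating_environment",
]


@dataclass(frozen=True)
class TwoStateParams:
    """Switching and division rates of the two-state model (per hour).

    Attributes
    ----------
    r : float
        Rising rate L -> H.
    f : float
        Falling rate H -> L.
    g_low, g_high : float
        Division rates of the L and H states.
    """

    r: float
    f: float
    g_low: float
    g_high: float

    def __post_init__(self) -> None:
        for name in ("r", "f", "g_low", "g_high"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.r < 0 or self.f < 0:
            raise ValueError("switching rates r, f must be non-negative")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.g_low - self.r, self.f], [self.r, self.g_high - self.f]]
        )


@dataclass
class SpectralSolution:
    """Eigen-decomposition of the two-state rate matrix.

    ``a1 >= a2`` are the eigenvalues; columns of ``eigenvectors`` are the
    corresponding (unnormalised) eigenvectors in ``(N_L, N_H)`` coordinates.
    """

    params: TwoStateParams
    a1: float
    a2: float
    eigenvectors: np.ndarray  # 2x2, columns v1, v2

    @property
    def stationary_fraction_high(self) -> float:
        """High-expressor fraction of the dominant eigenvector."""
        v = self.eigenvectors[:, 0]
        return float(v[1] / v.sum())

    @property
    def stationary_ratio(self) -> float:
        """Asymptotic subpopulation ratio R = N_L/N_H."""
        v = self.eigenvectors[:, 0]
        if v[1] == 0:
            return math.inf
        return float(v[0] / v[1])

    def propagate(self, n0: Sequence[float], t: np.ndarray | float) -> np.ndarray:
        """Population vector at times ``t`` starting from ``n0``.

        Returns an array of shape ``(len(t), 2)`` (or ``(2,)`` for scalar t).
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        n0 = np.asarray(n0, dtype=float)
        if abs(self.a1 - self.a2) < 1e-12 * max(1.0, abs(self.a1)):
            # (near-)defective matrix: fall back to the matrix exponential
            from scipy.linalg import expm

            out = np.stack([expm(self.params.matrix * ti) @ n0 for ti in t_arr])
        else:
            coeffs = np.linalg.solve(self.eigenvectors, n0)
            out = (
                coeffs[0] * np.exp(self.a1 * t_arr)[:, None] * self.eigenvectors[:, 0]
                + coeffs[1] * np.exp(self.a2 * t_arr)[:, None] * self.eigenvectors[:, 1]
            )
        return out[0] if np.isscalar(t) else out

    def propagate_log(self, frac0: Sequence[float], dt: float) -> tuple[np.ndarray, float]:
        """Advance a composition vector by ``dt`` in log-total coordinates.

        Parameters
        ----------
        frac0 : sequence of float
            Composition (need not be normalised; only the direction matters).
        dt : float

        Returns
        -------
        (fractions, log_gain) : the normalised composition after ``dt`` and
        the log of the total-population multiplication factor, computed
        without overflow for large ``a1 * dt``.
        """
        frac0 = np.asarray(frac0, dtype=float)
        total0 = frac0.sum()
        frac0 = frac0 / total0
        if abs(self.a1 - self.a2) < 1e-12 * max(1.0, abs(self.a1)):
            from scipy.linalg import expm

            n = expm(self.params.matrix * dt) @ frac0
        else:
            coeffs = np.linalg.solve(self.eigenvectors, frac0)
            # factor out e^{a1 dt} so only the decaying mode is exponentiated
            n = coeffs[0] * self.eigenvectors[:, 0] + coeffs[1] * np.exp(
                (self.a2 - self.a1) * dt
            ) * self.eigenvectors[:, 1]
        total = n.sum()
        if total <= 0:  # pragma: no cover - only for pathological rate sets
            raise FloatingPointError("population direction collapsed to zero")
        return n / total, self.a1 * dt + math.log(total)

    def ratio(self, t: np.ndarray | float, n0: Sequence[float]) -> np.ndarray:
        """Closed-form subpopulation ratio R(t) = N_L(t)/N_H(t) from ``n0``."""
        n = self.propagate(n0, np.atleast_1d(t))
        out = n[:, 0] / n[:, 1]
        return out if np.ndim(t) else float(out[0])


def solve_two_state(params: TwoStateParams) -> SpectralSolution:
    """Closed-form eigen-decomposition of the 2x2 two-state matrix.

    ``a_{1,2} = ((g_L - r + g_H - f) +/- sqrt((g_L - r - g_H + f)^2 + 4 r f)) / 2``.
    """
    gl, gh, r, f = params.g_low, params.g_high, params.r, params.f
    tr = (gl - r) + (gh - f)
    diff = (gl - r) - (gh - f)
    disc = math.sqrt(diff * diff + 4.0 * r * f)
    a1 = 0.5 * (tr + disc)
    a2 = 0.5 * (tr - disc)

    def eigvec(a: float) -> np.ndarray:
        # (A - aI) v = 0; pick whichever row gives the better-conditioned vector
        v = np.array([f, a - (gl - r)])
        if np.allclose(v, 0.0):
            v = np.array([a - (gh - f), r])
        if np.allclose(v, 0.0):
            # r = f = 0 and degenerate rows: coordinate axes are eigenvectors
            v = np.array([1.0, 0.0]) if a == gl else np.array([0.0, 1.0])
        return v / np.linalg.norm(v)

    v1, v2 = eigvec(a1), eigvec(a2)
    if abs(np.linalg.det(np.column_stack([v1, v2]))) < 1e-14:
        # shared eigenvector (defective); keep an orthogonal second column so
        # propagate() can detect the degeneracy and use expm instead
        v2 = np.array([-v1[1], v1[0]])
    return SpectralSolution(params=params, a1=a1, a2=a2, eigenvectors=np.column_stack([v1, v2]))


def population_fitness(params: TwoStateParams) -> float:
    """Asymptotic population growth rate: the dominant eigenvalue ``a_1``."""
    return solve_two_state(params).a1


# ---------------------------------------------------------------------------
# Sorting-relaxation data and switching-rate fitting
# ---------------------------------------------------------------------------

ARM_NAMES = ("high_sorted", "low_sorted", "unsorted")


@dataclass
class SortRelaxationData:
    """Subpopulation-ratio time courses after cell sorting.

    ``ratios`` maps each arm (high_sorted, low_sorted, unsorted) to the
    measured ratio R(t) = N_L/N_H on the shared time grid ``times``.
    """

    times: np.ndarray
    ratios: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for arm, rr in self.ratios.items():
            rr = np.asarray(rr, dtype=float)
            if rr.shape != self.times.shape:
                raise ValueError(f"arm {arm!r} does not share the time grid")
            if np.any(rr <= 0):
                raise ValueError(f"arm {arm!r} has non-positive ratios")
            self.ratios[arm] = rr


def normalize_log_ratios(data: SortRelaxationData) -> Dict[str, np.ndarray]:
    """Normalise sorted-arm log-ratios against the unsorted control.

    Each sorted arm's ln R(t) is divided pointwise by the unsorted arm's
    ln R(t) and rescaled by the mean unsorted log-ratio, which removes
    slow common-mode drift of the stationary distribution while preserving
    the overall scale.  The unsorted arm itself is returned untouched.
    """
    if "unsorted" not in data.ratios:
        raise ValueError("normalization requires the unsorted control arm")
    ln_u = np.log(data.ratios["unsorted"])
    if np.any(np.abs(ln_u) < 1e-12):
        raise ValueError("unsorted log-ratio crosses zero; cannot normalize")
    scale = ln_u.mean()
    out: Dict[str, np.ndarray] = {}
    for arm, rr in data.ratios.items():
        ln = np.log(rr)
        out[arm] = ln if arm == "unsorted" else ln / ln_u * scale
    return out


@dataclass
class SwitchingRateFit:
    """Result of fitting (r, f) to sorting-relaxation log-ratios."""

    params: TwoStateParams
    sse: float
    ci_r: tuple[float, float] | None = None
    ci_f: tuple[float, float] | None = None
    n_boot: int = 0


def _sorted_arm_residuals(
    log_rf: np.ndarray,
    times: np.ndarray,
    ln_obs: Mapping[str, np.ndarray],
    g_low: float,
    g_high: float,
) -> float:
    r, f = np.exp(log_rf)
    if not (np.isfinite(r) and np.isfinite(f)):
        return 1e12
    sol = solve_two_state(TwoStateParams(r=r, f=f, g_low=g_low, g_high=g_high))
    sse = 0.0
    for arm, ln_r in ln_obs.items():
        if arm == "unsorted":
            continue
        r0 = math.exp(ln_r[0])
        n0 = np.array([r0 / (1.0 + r0), 1.0 / (1.0 + r0)])
        pred = sol.propagate(n0, times)
        with np.errstate(divide="ignore", invalid="ignore"):
            ln_pred = np.log(pred[:, 0] / pred[:, 1])
        if not np.all(np.isfinite(ln_pred)):
            return 1e12
        sse += float(np.sum((ln_pred[1:] - ln_r[1:]) ** 2))
    return sse


def fit_switching_rates(
    data: SortRelaxationData,
    g_low: float,
    g_high: float,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> SwitchingRateFit:
    """Estimate switching rates (r, f) from sorting-relaxation time courses.

    The measured log-ratios of both sorted arms are normalised against the
    unsorted control, then jointly fit with Nelder-Mead least squares in
    (log r, log f); the initial condition of each arm is taken from its
    observed ratio at t = 0.  Confidence intervals come from case resampling
    of post-sort time points.

    Parameters
    ----------
    g_low, g_high : float
        State-level division rates, held fixed during the fit.
    n_boot : int
        Parametric-bootstrap draws for the confidence intervals (0 disables
        them).  Each draw regenerates all three arms from the fitted model
        with multiplicative log-normal noise at the residual-estimated
        level and refits; this propagates every noise component, including
        the measured t=0 composition and the unsorted-arm normalization,
        which a resampling bootstrap over time points cannot see.
    """
    sorted_arms = [a for a in data.ratios if a != "unsorted"]
    if not sorted_arms:
        raise ValueError("need at least one sorted arm")
    for arm in sorted_arms:
        if len(data.times) < 4:
            raise ValueError("need >= 4 time points per sorted arm")
    ln_obs = normalize_log_ratios(data)

    def minimize_from(x0: np.ndarray) -> optimize.OptimizeResult:
        return optimize.minimize(
            _sorted_arm_residuals,
            x0,
            args=(data.times, ln_obs, g_low, g_high),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
        )

    starts = [
        np.log([r0, f0])
        for r0 in (1e-3, 1e-2, 1e-1)
        for f0 in (1e-4, 1e-3, 1e-2)
    ]
    best = None
    for x0 in starts:
        res = minimize_from(x0)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"switching-rate fit failed to converge: {best}")
    r_hat, f_hat = np.exp(best.x)
    fit = SwitchingRateFit(
        params=TwoStateParams(r=r_hat, f=f_hat, g_low=g_low, g_high=g_high),
        sse=float(best.fun),
    )

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        sol_hat = solve_two_state(fit.params)
        # model curves per arm from the observed t=0 compositions (raw scale)
        model_ln: Dict[str, np.ndarray] = {}
        resid: list[float] = []
        for arm, rr in data.ratios.items():
            if arm == "unsorted":
                pred = np.full_like(data.times, math.log(sol_hat.stationary_ratio))
            else:
                r0 = rr[0]
                n0 = np.array([r0 / (1.0 + r0), 1.0 / (1.0 + r0)])
                pred = np.log(np.asarray(sol_hat.ratio(data.times, n0)))
            model_ln[arm] = pred
            resid.extend(np.log(rr[1:]) - pred[1:])
        dof = max(len(resid) - 2, 1)
        sigma = math.sqrt(float(np.sum(np.square(resid))) / dof)

        draws = np.empty((n_boot, 2))
        for b in range(n_boot):
            sim = SortRelaxationData(
                times=data.times,
                ratios={
                    arm: np.exp(ln + sigma * rng.standard_normal(len(ln)))
                    for arm, ln in model_ln.items()
                },
            )
            sim_ln = normalize_log_ratios(sim)
            res = optimize.minimize(
                _sorted_arm_residuals,
                best.x,
                args=(data.times, sim_ln, g_low, g_high),
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
            )
            draws[b] = np.exp(res.x)
        lo = (1.0 - ci_level) / 2.0
        fit.ci_r = tuple(np.quantile(draws[:, 0], [lo, 1.0 - lo]))
        fit.ci_f = tuple(np.quantile(draws[:, 1], [lo, 1.0 - lo]))
        fit.n_boot = n_boot
    return fit


# ---------------------------------------------------------------------------
# Lineage statistics
# ---------------------------------------------------------------------------


def lineage_occupancy(
    params: TwoStateParams,
    p0_high: float = 0.5,
    window: float | None = None,
) -> float:
    """Time-averaged probability that a single lineage is in the high state.

    A lineage switches L -> H at rate r and H -> L at rate f with no fitness
    weighting, so ``dp_H/dt = r (1 - p_H) - f p_H``.  With ``k = r + f`` the
    closed-form window average over [0, T] is

        p_inf + (p0 - p_inf) (1 - e^{-kT}) / (kT),   p_inf = r / k.

    ``window=None`` (or infinite) returns the asymptotic occupancy r/(r+f).
    """
    if not 0.0 <= p0_high <= 1.0:
        raise ValueError("p0_high must be a probability")
    k = params.r + params.f
    if k == 0:
        return p0_high  # degenerate: no switching at all
    p_inf = params.r / k
    if window is None or math.isinf(window):
        return p_inf
    if window <= 0:
        raise ValueError("window must be positive")
    kt = k * window
    return p_inf + (p0_high - p_inf) * (1.0 - math.exp(-kt)) / kt


def rates_from_memory(tau_low: float, tau_high: float) -> tuple[float, float]:
    """Switching rates from cellular memories: r = 1/tau_L, f = 1/tau_H.

    Infinite memory maps to a zero rate.
    """
    if tau_low <= 0 or tau_high <= 0:
        raise ValueError("memories must be positive")
    r = 0.0 if math.isinf(tau_low) else 1.0 / tau_low
    f = 0.0 if math.isinf(tau_high) else 1.0 / tau_high
    return r, f


# ---------------------------------------------------------------------------
# Fluctuating environments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Alternation between a 'normal' and a 'toxic' environment.

    ``kind='periodic'`` alternates deterministically with the given mean
    durations; ``kind='random'`` draws exponential durations with those
    means.  Episodes always start with the normal environment.
    """

    kind: Literal["periodic", "random"]
    mean_normal_h: float
    mean_toxic_h: float

    def __post_init__(self) -> None:
        if self.mean_normal_h <= 0 or self.mean_toxic_h <= 0:
            raise ValueError("mean durations must be positive")
        if self.kind not in ("periodic", "random"):
            raise ValueError("kind must be 'periodic' or 'random'")


def _segment_durations(
    schedule: EnvironmentSchedule, horizon: float, rng: np.random.Generator
) -> list[tuple[str, float]]:
    segs: list[tuple[str, float]] = []
    t = 0.0
    env = "normal"
    means = {"normal": schedule.mean_normal_h, "toxic": schedule.mean_toxic_h}
    while t < horizon:
        dur = (
            means[env]
            if schedule.kind == "periodic"
            else float(rng.exponential(means[env]))
        )
        dur = min(dur, horizon - t)
        if dur > 0:
            segs.append((env, dur))
        t += dur
        env = "toxic" if env == "normal" else "normal"
    return segs


def simulate_fluctuating_environment(
    params_by_env: Mapping[str, TwoStateParams],
    schedule: EnvironmentSchedule,
    horizon: float,
    seed: int = 0,
    n_reps: int = 20,
    frac0_high: float | None = None,
) -> float:
    """Long-run population fitness under an alternating environment.

    The two-state system is integrated piecewise (one matrix exponential per
    environment episode) in log-population coordinates, so the result never
    overflows.  Returns ``ln(N(horizon)/N(0)) / horizon``, averaged over
    ``n_reps`` realizations for random schedules (periodic schedules are
    deterministic and simulated once).

    ``params_by_env`` must provide entries for ``'normal'`` and ``'toxic'``.
    """
    for env in ("normal", "toxic"):
        if env not in params_by_env:
            raise ValueError(f"params_by_env must define {env!r}")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    sols = {env: solve_two_state(p) for env, p in params_by_env.items()}
    if frac0_high is None:
        frac0_high = max(0.0, min(1.0, sols["normal"].stationary_fraction_high))
    reps = 1 if schedule.kind == "periodic" else n_reps
    rng = np.random.default_rng(seed)
    fitnesses = np.empty(reps)
    for i in range(reps):
        frac = np.array([1.0 - frac0_high, frac0_high])
        log_total = 0.0
        for env, dur in _segment_durations(schedule, horizon, rng):
            frac, gain = sols[env].propagate_log(frac, dur)
            log_total += gain
        fitnesses[i] = log_total / horizon
    return float(fitnesses.mean())
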