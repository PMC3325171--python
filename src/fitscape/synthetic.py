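"""Synthetic inputs with known ground truth for the whole pipeline.

Generators for every data type the analysis consumes:

* exact (event-driven) stochastic realisations of the two-state
  birth-switch process, for populations and for single-cell lineages;
* stationary flow-cytometry event tables drawn from a two-component
  log-normal fluorescence mixture with correlated log-normal scatter;
* exponential growth curves with multiplicative count noise, sampled on
  the 12-hour resuspension grid;
* post-sorting relaxation time courses from the closed-form two-state
  solution.

The module also defines the calibrated study system used throughout the
package's benchmarks: a dose-response family of mixtures whose
high-expressor fraction rises with the inducer (ATc) concentration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cytometry import EventTable
from .growth import GrowthCurve
from .fitness import Condition
from .twostate import SortRelaxationData, TwoStateParams, solve_two_state

__all__ = [
    "MixtureSpec",
    "SimConfig",
    "PopulationTrajectory",
    "LineageTrace",
    "simulate_birth_switch_population",
    "simulate_lineage",
    "generate_stationary_events",
    "generate_growth_curve",
    "generate_sorting_experiment",
    "stationary_fraction_high",
    "mixture_for_atc",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Two-component log-normal fluorescence mixture (log10 scale).

    ``low_mode_location``/``high_mode_location`` are the modal fluorescences
    (a.u.) of the two expression states; ``log_sd_*`` their spreads in
    decades.  Scatter channels are drawn from a correlated bivariate
    log-normal shared by both components.
    """

    low_mode_location: float = 3.0
    high_mode_location: float = 500.0
    log_sd_low: float = 0.25
    log_sd_high: float = 0.20
    fraction_high: float = 0.5
    n_events: int = 20_000
    fsc_log_loc: float = 2.0
    ssc_log_loc: float = 1.8
    scatter_log_sd: float = 0.15
    scatter_corr: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_high <= 1.0:
            raise ValueError("fraction_high must be a probability")
        if self.low_mode_location <= 0 or self.high_mode_location <= 0:
            raise ValueError("mode locations must be positive")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not -1.0 < self.scatter_corr < 1.0:
            raise ValueError("scatter correlation must be in (-1, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Simulation plumbing: seed, duration and sampling grid.

    ``record_interval_h`` defaults to the 12-hour resuspension schedule of
    the growth experiments; ``noise_cv`` is the multiplicative
    coefficient of variation of count measurements (hemocytometer-scale
    error, default 5%).
    """

    seed: int = 0
    duration_h: float = 72.0
    record_interval_h: float = 12.0
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.duration_h <= 0 or self.record_interval_h <= 0:
            raise ValueError("duration and record interval must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")

    @property
    def record_times(self) -> np.ndarray:
        n = int(math.floor(self.duration_h / self.record_interval_h + 1e-9))
        return np.arange(n + 1) * self.record_interval_h


@dataclass
class PopulationTrajectory:
    """Recorded (N_L, N_H) of a birth-switch realisation.

    When the simulation dilutes the culture to keep it in log phase,
    ``log_dilution`` accumulates the log of the removed multiplication
    factor, so ``effective_total = (n_low + n_high) * exp(log_dilution)``
    is the undiluted (virtual) cell count used for fitness estimation.
    """

    times: np.ndarray
    n_low: np.ndarray
    n_high: np.ndarray
    log_dilution: np.ndarray
    extinct: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.n_low < 0) or np.any(self.n_high < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> np.ndarray:
        return self.n_low + self.n_high

    @property
    def log_effective_total(self) -> np.ndarray:
        return np.log(self.total) + self.log_dilution

    @property
    def fraction_high(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.n_high / self.total


def simulate_birth_switch_population(
    params: TwoStateParams,
    n0_low: int,
    n0_high: int,
    config: SimConfig,
    max_population: int | None = None,
    dilution_target: int | None = None,
) -> PopulationTrajectory:
    """Exact event-driven simulation of the birth-switch process.

    Four reactions: L division (rate g_L N_L), H division (g_H N_H),
    rise L -> H (r N_L) and fall H -> L (f N_H).  The expectation of the
    process obeys the two-state linear ODEs.

    If ``max_population`` is set, the culture is binomially diluted down to
    ``dilution_target`` (default: the initial size) whenever the total
    exceeds the cap at a record time, emulating resuspension into fresh
    medium; the removed factor accumulates in ``log_dilution``.
    Extinction truncates the trajectory and sets the ``extinct`` flag.
    """
    if n0_low < 0 or n0_high < 0 or n0_low + n0_high < 1:
        raise ValueError("need at least one founder cell")
    rng = np.random.default_rng(config.seed)
    record_times = config.record_times
    if dilution_target is None and max_population is not None:
        dilution_target = n0_low + n0_high

    n_l, n_h = int(n0_low), int(n0_high)
    t = 0.0
    log_dil = 0.0
    rec_l, rec_h, rec_d = [n_l], [n_h], [0.0]
    gl, gh, r, f = params.g_low, params.g_high, params.r, params.f
    for t_next in record_times[1:]:
        while True:
            rates = (gl * n_l, gh * n_h, r * n_l, f * n_h)
            total_rate = sum(rates)
            if total_rate == 0.0:
                break
            t_event = t + rng.exponential(1.0 / total_rate)
            if t_event >= t_next:
                break
            t = t_event
            u = rng.random() * total_rate
            if u < rates[0]:
                n_l += 1
            elif u < rates[0] + rates[1]:
                n_h += 1
            elif u < rates[0] + rates[1] + rates[2]:
                n_l -= 1
                n_h += 1
            else:
                n_l += 1
                n_h -= 1
        t = t_next
        if n_l + n_h == 0:
            # extinction: truncate at the last recorded point
            times = record_times[: len(rec_l)]
            return PopulationTrajectory(
                times=times,
                n_low=np.array(rec_l, dtype=float),
                n_high=np.array(rec_h, dtype=float),
                log_dilution=np.array(rec_d),
                extinct=True,
            )
        if max_population is not None and n_l + n_h > max_population:
            keep = dilution_target / (n_l + n_h)
            new_l = int(rng.binomial(n_l, keep))
            new_h = int(rng.binomial(n_h, keep))
            if new_l + new_h == 0:  # keep at least one cell after dilution
                new_l, new_h = (1, 0) if n_l >= n_h else (0, 1)
            log_dil += math.log((n_l + n_h) / (new_l + new_h))
            n_l, n_h = new_l, new_h
        rec_l.append(n_l)
        rec_h.append(n_h)
        rec_d.append(log_dil)
    return PopulationTrajectory(
        times=record_times,
        n_low=np.array(rec_l, dtype=float),
        n_high=np.array(rec_h, dtype=float),
        log_dilution=np.array(rec_d),
        extinct=False,
    )


@dataclass
class LineageTrace:
    """Switching history of one cell lineage.

    ``states[i]`` is occupied on ``[switch_times[i], switch_times[i+1])``
    with ``switch_times[0] = 0`` and the final sojourn censored at
    ``total_duration``.
    """

    switch_times: np.ndarray
    states: list[str]
    total_duration: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.states) != len(self.switch_times):
            raise ValueError("one state per switch time required")
        if np.any(np.diff(self.switch_times) <= 0):
            raise ValueError("switch_times must be increasing")
        for a, b in zip(self.states, self.states[1:]):
            if a == b:
                raise ValueError("states must alternate")

    def occupancy(self, state: str = "H") -> float:
        """Fraction of total_duration spent in ``state``."""
        bounds = np.append(self.switch_times, self.total_duration)
        durations = np.diff(bounds)
        mask = np.array([s == state for s in self.states])
        return float(durations[mask].sum() / self.total_duration)

    def holding_times(self, state: str) -> np.ndarray:
        """Completed (uncensored) sojourn durations in ``state``."""
        bounds = np.append(self.switch_times, self.total_duration)
        durations = np.diff(bounds)[:-1]  # last sojourn is censored
        mask = np.array([s == state for s in self.states[:-1]])
        return durations[mask]


def simulate_lineage(
    params: TwoStateParams, config: SimConfig, start_state: str | None = None
) -> LineageTrace:
    """Single-lineage switching trajectory (no fitness weighting).

    Holding times are exponential with mean 1/r in L and 1/f in H.  With
    both rates zero the trace is degenerate (a single state) and flagged.
    By default the initial state is drawn from the stationary occupancy
    r/(r+f).
    """
    r, f = params.r, params.f
    rng = np.random.default_rng(config.seed)
    if start_state is None:
        p_high = r / (r + f) if r + f > 0 else 0.5
        start_state = "H" if rng.random() < p_high else "L"
    if start_state not in ("L", "H"):
        raise ValueError("start_state must be 'L' or 'H'")
    if r == 0.0 and f == 0.0:
        warnings.warn("r = f = 0: degenerate single-state lineage", stacklevel=2)
        return LineageTrace(np.array([0.0]), [start_state], config.duration_h, degenerate=True)
    times = [0.0]
    states = [start_state]
    t = 0.0
    state = start_state
    while True:
        rate = r if state == "L" else f
        if rate == 0.0:
            break  # absorbed for the remaining duration
        t += rng.exponential(1.0 / rate)
        if t >= config.duration_h:
            break
        state = "H" if state == "L" else "L"
        times.append(t)
        states.append(state)
    return LineageTrace(np.array(times), states, config.duration_h)


def generate_stationary_events(spec: MixtureSpec, seed: int) -> EventTable:
    """Draw a stationary event table from the log-normal mixture.

    The number of high-mode events is binomial in ``fraction_high``;
    fluorescence is log10-normal around each mode, scatter is a shared
    correlated bivariate log-normal, and rows are shuffled.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_events
    n_high = int(rng.binomial(n, spec.fraction_high))
    log_f = np.concatenate(
        [
            rng.normal(math.log10(spec.low_mode_location), spec.log_sd_low, n - n_high),
            rng.normal(math.log10(spec.high_mode_location), spec.log_sd_high, n_high),
        ]
    )
    cov = (spec.scatter_log_sd ** 2) * np.array(
        [[1.0, spec.scatter_corr], [spec.scatter_corr, 1.0]]
    )
    scatter = rng.multivariate_normal(
        [spec.fsc_log_loc, spec.ssc_log_loc], cov, size=n, method="cholesky"
    )
    perm = rng.permutation(n)
    return EventTable(
        fl1=10.0 ** log_f[perm],
        fsc=10.0 ** scatter[perm, 0],
        ssc=10.0 ** scatter[perm, 1],
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def generate_growth_curve(
    g_true: float,
    n0: float,
    config: SimConfig,
    condition: Condition | None = None,
) -> GrowthCurve:
    """Exponential growth curve N0 e^{g t} with multiplicative count noise."""
    if n0 <= 0:
        raise ValueError("initial density must be positive")
    rng = np.random.default_rng(config.seed)
    t = config.record_times
    counts = n0 * np.exp(g_true * t) * _lognormal_noise(rng, config.noise_cv, t.size)
    return GrowthCurve(times=t, counts=counts, condition=condition)


def generate_sorting_experiment(
    params: TwoStateParams, purity: float = 0.99, config: SimConfig = SimConfig()
) -> SortRelaxationData:
    """Post-sorting relaxation of subpopulation ratios R(t) = N_L/N_H.

    Three arms share the sampling grid: high-sorted (fraction ``purity`` in
    H at t=0), low-sorted (``purity`` in L) and the unsorted control, which
    starts on the stationary composition.  Ratios follow the closed-form
    two-state solution with multiplicative log-normal noise.
    """
    if not 0.5 < purity <= 1.0:
        raise ValueError("purity must be in (0.5, 1]")
    # a perfectly pure sort would make the t=0 ratio of one arm infinite;
    # cap just below 1 so ratios stay finite (indistinguishable in practice)
    purity = min(purity, 1.0 - 1e-12)
    sol = solve_two_state(params)
    t = config.record_times
    rng = np.random.default_rng(config.seed)
    pi_h = sol.stationary_fraction_high
    ics = {
        "high_sorted": np.array([1.0 - purity, purity]),
        "low_sorted": np.array([purity, 1.0 - purity]),
        "unsorted": np.array([1.0 - pi_h, pi_h]),
    }
    ratios = {}
    for arm, n0 in ics.items():
        rr = np.asarray(sol.ratio(t, n0))
        ratios[arm] = rr * _lognormal_noise(rng, config.noise_cv, t.size)
    return SortRelaxationData(times=t, ratios=ratios)


# ---------------------------------------------------------------------------
# Calibrated study system: inducer dose response of the mixture
# ---------------------------------------------------------------------------

#: Hill parameters of the high-expressor fraction versus ATc: fraction_high =
#: FH_MAX * C^2 / (FH_K2 + C^2).  Chosen once so induction is bistable above
#: ~1 ng/ml, balanced (50/50) at 10 ng/ml, and saturating near 80%.
FH_MAX = 0.8
FH_K2 = 60.0


def stationary_fraction_high(atc_ng_ml: float) -> float:
    """High-expressor fraction of the stationary mixture at a given ATc."""
    if atc_ng_ml < 0:
        raise ValueError("ATc must be non-negative")
    c2 = atc_ng_ml * atc_ng_ml
    return FH_MAX * c2 / (FH_K2 + c2)


def mixture_for_atc(atc_ng_ml: float, n_events: int = 100_000) -> MixtureSpec:
    """Stationary mixture emulating the circuit's ATc dose response."""
    return MixtureSpec(fraction_high=stationary_fraction_high(atc_ng_ml), n_events=n_events)
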