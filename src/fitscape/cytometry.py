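"""Flow-cytometry event processing: gating, histograms, bimodality, summaries.

The pipeline mirrors standard flow practice for a strongly bimodal reporter:

1. an elliptical scatter gate (2-D Gaussian fit to log scatter, keep events
   where the fitted density exceeds a fraction of its maximum) removes cell
   size/cycle outliers;
2. fluorescence is binned on a log axis and smoothed with a moving average;
3. a z-test-based bimodality criterion finds valley candidates between
   local maxima and picks the classification threshold;
4. events are classified into low/high expressors and summarised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "EventTable",
    "FluorescenceDistribution",
    "BimodalityResult",
    "SubpopulationSummary",
    "gate_events",
    "build_histogram",
    "smooth_histogram",
    "bimodality_test",
    "select_threshold",
    "classify_subpopulations",
    "summary_stats",
    "subpopulation_means_from_distribution",
    "DEFAULT_THRESHOLD",
]

#: Constant classification threshold (fluorescence a.u.) used when the
#: bimodality test finds no valley; the value separating low and high
#: expressors of the reference circuit at intermediate induction.
DEFAULT_THRESHOLD = 50.0


@dataclass
class EventTable:
    """Per-cell measurements: fluorescence (FL1) and forward/side scatter.

    All channels must be strictly positive (log-transformable).
    """

    fl1: np.ndarray
    fsc: np.ndarray
    ssc: np.ndarray

    def __post_init__(self) -> None:
        self.fl1 = np.asarray(self.fl1, dtype=float)
        self.fsc = np.asarray(self.fsc, dtype=float)
        self.ssc = np.asarray(self.ssc, dtype=float)
        if not (self.fl1.shape == self.fsc.shape == self.ssc.shape):
            raise ValueError("channel arrays must have identical shape")
        for name in ("fl1", "fsc", "ssc"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} values must be strictly positive")

    def __len__(self) -> int:
        return self.fl1.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"FSC": self.fsc, "SSC": self.ssc, "FL1": self.fl1})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        return cls(fl1=df["FL1"].to_numpy(), fsc=df["FSC"].to_numpy(), ssc=df["SSC"].to_numpy())

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "EventTable":
        return cls.from_frame(pd.read_csv(path))


def gate_events(events: EventTable, gate_fraction: float = 0.90) -> EventTable:
    """Elliptical scatter gate at ``gate_fraction`` of the maximal density.

    Fits a 2-D Gaussian to (log SSC, log FSC) and keeps events where the
    fitted density is at least ``gate_fraction`` times its maximum, i.e.
    squared Mahalanobis distance <= -2 ln(gate_fraction).  For truly
    Gaussian log-scatter this retains a fraction ``1 - gate_fraction`` of
    events (chi-squared with 2 degrees of freedom).
    """
    if len(events) < 100:
        raise ValueError("need >= 100 events to fit the scatter gate")
    if not 0.0 <= gate_fraction < 1.0:
        raise ValueError("gate_fraction must lie in [0, 1)")
    if gate_fraction == 0.0:
        return events
    x = np.column_stack([np.log(events.ssc), np.log(events.fsc)])
    mu = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    det = np.linalg.det(cov)
    if not np.isfinite(det) or det <= 0:
        raise ValueError("singular scatter covariance; cannot gate")
    cov_inv = np.linalg.inv(cov)
    centred = x - mu
    maha_sq = np.einsum("ij,jk,ik->i", centred, cov_inv, centred)
    keep = maha_sq <= -2.0 * math.log(gate_fraction)
    if keep.sum() < 100:
        warnings.warn(f"only {int(keep.sum())} events remain after gating", stacklevel=2)
    return EventTable(fl1=events.fl1[keep], fsc=events.fsc[keep], ssc=events.ssc[keep])


@dataclass
class FluorescenceDistribution:
    """Binned fluorescence distribution with optional smoothed counts.

    Bins are half-open ``[lo, hi)`` and log-spaced.  ``counts`` are raw
    event counts per bin; ``smoothed_counts`` appear after smoothing.
    ``n_dropped`` counts events outside the histogram range.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed_counts: np.ndarray | None = None
    smooth_window: int | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("bin_edges must have len(counts) + 1 entries")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.smoothed_counts is not None:
            self.smoothed_counts = np.asarray(self.smoothed_counts, dtype=float)
            if self.smoothed_counts.size != self.counts.size:
                raise ValueError("smoothed_counts length must equal counts length")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def bin_centers(self) -> np.ndarray:
        """Geometric bin centres (natural for log-spaced bins)."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def probability(self, smoothed: bool = False) -> np.ndarray:
        """Probability mass per bin, normalised to sum to one."""
        c = self._active_counts(smoothed)
        total = c.sum()
        if total == 0:
            raise ValueError("empty distribution has no probability")
        return c / total

    def _active_counts(self, smoothed: bool) -> np.ndarray:
        if smoothed:
            if self.smoothed_counts is None:
                raise ValueError("distribution has not been smoothed")
            return self.smoothed_counts
        return self.counts

    def bin_index(self, value: float) -> int:
        """Index of the half-open bin containing ``value``."""
        if not self.bin_edges[0] <= value < self.bin_edges[-1]:
            raise ValueError(f"{value} outside histogram range")
        return int(np.searchsorted(self.bin_edges, value, side="right") - 1)


def build_histogram(
    events: EventTable,
    n_bins: int = 256,
    fl_range: tuple[float, float] = (1.0, 1.0e4),
) -> FluorescenceDistribution:
    """Log-spaced fluorescence histogram; out-of-range events are dropped."""
    lo, hi = fl_range
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi for a log-spaced range")
    edges = np.logspace(math.log10(lo), math.log10(hi), n_bins + 1)
    f = events.fl1
    in_range = (f >= lo) & (f < hi)
    counts, _ = np.histogram(f[in_range], bins=edges)
    return FluorescenceDistribution(
        bin_edges=edges, counts=counts.astype(float), n_dropped=int((~in_range).sum())
    )


def smooth_histogram(dist: FluorescenceDistribution, window: int = 32) -> FluorescenceDistribution:
    """Centred moving average over histogram bins.

    Interior bins average ``window`` neighbours (window [i - w//2, i + w - w//2));
    edge bins average over whatever part of the window is available, so the
    total mass is preserved only up to edge effects.
    """
    if not 1 <= window <= dist.n_bins:
        raise ValueError("window must be in [1, n_bins]")
    n = dist.n_bins
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(dist.counts)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + (window - half), n)
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return FluorescenceDistribution(
        bin_edges=dist.bin_edges,
        counts=dist.counts,
        smoothed_counts=smoothed,
        smooth_window=window,
        n_dropped=dist.n_dropped,
    )


@dataclass
class BimodalityResult:
    """Outcome of the valley-depth bimodality test.

    ``candidate_thresholds`` are fluorescence values of interior minima that
    lie strictly between two local maxima; ``z_scores`` holds the (left,
    right) z statistics of each candidate against its flanking maxima.
    """

    is_bimodal: bool
    candidate_thresholds: np.ndarray
    z_scores: np.ndarray  # shape (n_candidates, 2)
    selected_threshold: float | None = None


def bimodality_test(
    dist: FluorescenceDistribution, z_crit: float = 4.0
) -> BimodalityResult:
    """Test whether the smoothed histogram has a significant valley.

    Smoothed per-bin counts are treated as normal with variance equal to
    the expectation divided by the smoothing window (Poisson counts
    averaged over ``window`` bins).  For each interior minimum between two
    local maxima, z = (mu_max - mu_min) / sqrt((mu_max + mu_min) / window)
    is computed against each flanking maximum; the histogram is bimodal iff
    some minimum has both z-scores above ``z_crit``.
    """
    if dist.smoothed_counts is None:
        raise ValueError("bimodality test requires smoothed counts")
    y = dist.smoothed_counts
    window = dist.smooth_window or 32
    maxima, _ = find_peaks(y)
    minima, _ = find_peaks(-y)
    if len(maxima) < 2 or len(minima) < 1:
        return BimodalityResult(False, np.empty(0), np.empty((0, 2)))

    centers = dist.bin_centers
    cands: list[float] = []
    zs: list[tuple[float, float]] = []
    for m in minima:
        left = maxima[maxima < m]
        right = maxima[maxima > m]
        if len(left) == 0 or len(right) == 0:
            continue
        # deepest valley criterion uses the tallest flanking maxima
        pl = left[np.argmax(y[left])]
        pr = right[np.argmax(y[right])]
        z_pair = tuple(
            (y[p] - y[m]) / math.sqrt((y[p] + y[m]) / window) if y[p] + y[m] > 0 else 0.0
            for p in (pl, pr)
        )
        cands.append(float(centers[m]))
        zs.append(z_pair)
    if not cands:
        return BimodalityResult(False, np.empty(0), np.empty((0, 2)))
    order = np.argsort(cands)
    thresholds = np.asarray(cands)[order]
    z_arr = np.asarray(zs)[order]
    accepted = np.all(z_arr > z_crit, axis=1)
    result = BimodalityResult(bool(accepted.any()), thresholds, z_arr)
    if result.is_bimodal:
        result.selected_threshold = select_threshold(result)
    return result


def select_threshold(result: BimodalityResult) -> float:
    """Choose the valley maximising the product of the two z-scores.

    Ties break toward lower fluorescence (candidates are sorted ascending,
    and argmax returns the first maximiser).
    """
    if not result.is_bimodal:
        raise ValueError(
            "distribution is not bimodal; use the constant-threshold fallback "
            f"(DEFAULT_THRESHOLD = {DEFAULT_THRESHOLD} a.u.)"
        )
    products = np.prod(result.z_scores, axis=1)
    ok = np.all(result.z_scores > 4.0, axis=1)
    products = np.where(ok, products, -np.inf)
    return float(result.candidate_thresholds[int(np.argmax(products))])


@dataclass(frozen=True)
class SubpopulationSummary:
    """Counts, ratio and moments of the low/high expressor split."""

    n_low: int
    n_high: int
    ratio: float  # N_L / N_H; inf when N_H == 0
    ratio_is_infinite: bool
    mean_low: float
    mean_high: float
    mean: float
    cv: float


def classify_subpopulations(events: EventTable, theta: float) -> SubpopulationSummary:
    """Split events at threshold theta: F < theta is low, F >= theta high."""
    if theta <= 0:
        raise ValueError("threshold must be positive")
    f = events.fl1
    low = f < theta
    n_low, n_high = int(low.sum()), int((~low).sum())
    if n_high == 0:
        ratio, inf_flag = math.inf, True
    else:
        ratio, inf_flag = n_low / n_high, False
    mu = float(f.mean())
    cv = float(f.std(ddof=0) / mu)
    return SubpopulationSummary(
        n_low=n_low,
        n_high=n_high,
        ratio=ratio,
        ratio_is_infinite=inf_flag,
        mean_low=float(f[low].mean()) if n_low else math.nan,
        mean_high=float(f[~low].mean()) if n_high else math.nan,
        mean=mu,
        cv=cv,
    )


def summary_stats(events: EventTable, ddof: int = 0) -> tuple[float, float]:
    """Mean and coefficient of variation of fluorescence.

    The population-SD convention (ddof=0) is the default; pass ddof=1 for
    the sample SD.
    """
    if len(events) < 2:
        raise ValueError("need >= 2 events for summary statistics")
    f = events.fl1
    mu = float(f.mean())
    return mu, float(f.std(ddof=ddof) / mu)


def subpopulation_means_from_distribution(
    dist: FluorescenceDistribution, theta: float, smoothed: bool = True
) -> tuple[float, float]:
    """Representative fluorescences of the low/high sides of a histogram.

    Count-weighted mean bin-centre fluorescence below and above ``theta``
    computed from the (smoothed) histogram; this stays defined even when no
    raw event falls on one side.  A side with zero mass falls back to the
    threshold itself.
    """
    c = dist._active_counts(smoothed)
    centers = dist.bin_centers
    high = centers >= theta
    means = []
    for mask in (~high, high):
        w = c[mask]
        means.append(float(np.average(centers[mask], weights=w)) if w.sum() > 0 else float(theta))
    return means[0], means[1]
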