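"""Shared fixtures: the calibrated induction series and derived memory table."""

from __future__ import annotations

import numpy as np
import pytest

import fitscape as fs

#: ATc levels (ng/ml) of the calibrated dose-response used across the suite.
ATC_LEVELS = tuple(float(c) for c in range(0, 21, 2))

#: Switching rates fitted for the circuit at 10 ng/ml induction (per hour).
R_INDUCTION = 28.5e-3
F_INDUCTION = 0.7e-3


@pytest.fixture(scope="session")
def dose_dists() -> dict[float, fs.FluorescenceDistribution]:
    """Smoothed stationary distributions per inducer level (fixed seeds)."""
    dists = {}
    for i, c in enumerate(ATC_LEVELS):
        events = fs.generate_stationary_events(
            fs.mixture_for_atc(c, n_events=100_000), seed=100 + i
        )
        dists[c] = fs.smooth_histogram(fs.build_histogram(events))
    return dists


@pytest.fixture(scope="session")
def memory_table(dose_dists):
    """Cellular-memory dose response of the calibrated series."""
    return fs.memory_dose_response(dose_dists)


@pytest.fixture(scope="session")
def induction_point_params() -> fs.TwoStateParams:
    """Two-state rates at 10 ng/ml: fitted switching rates, model division rates."""
    g_low = fs.DEFAULT_G0 * float(fs.gamma2(3.2, 10.0))
    g_high = fs.DEFAULT_G0 * float(fs.gamma2(500.0, 10.0))
    return fs.TwoStateParams(r=R_INDUCTION, f=F_INDUCTION, g_low=g_low, g_high=g_high)
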