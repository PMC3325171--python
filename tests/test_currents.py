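"""Cellular currents and memory estimation against first-passage oracles."""

import math
import warnings

import numpy as np
import pytest

import fitscape as fs
from fitscape.currents import (
    downward_current,
    fitness_corrected_currents,
    kernel_smooth,
    memory_from_currents,
)
from fitscape.fitness import ATcModelParams, Condition

G0 = 0.35
NEUTRAL = ATcModelParams(alpha=0.0, g0=G0)  # uniform fitness: dilution at g0
ORIGIN = Condition(0.0, 0.0)


def simulate_expression_process(r, f, g, low_level, high_level, theta,
                                n_cells, t_end, seed):
    """Independent oracle: single-cell expression with a two-state promoter.

    Within a state, fluorescence relaxes deterministically toward the state's
    steady level at the dilution rate g (dF/dt = k_state - g F); the promoter
    switches L->H at rate r and H->L at rate f.  Threshold crossings are
    solved analytically within each segment.  Returns the final fluorescence
    snapshot, the completed sojourn durations above/below theta, and the
    downward crossing rate per cell-hour.
    """
    rng = np.random.default_rng(seed)
    pi_h = r / (r + f)
    levels = {False: low_level, True: high_level}
    snap = np.empty(n_cells)
    above, below = [], []
    n_down = 0
    for i in range(n_cells):
        state = bool(rng.random() < pi_h)
        fl = levels[state]
        t, t_side = 0.0, 0.0
        side = fl >= theta
        settled = False
        while True:
            rate = f if state else r
            dt = rng.exponential(1.0 / rate)
            t_next = min(t + dt, t_end)
            k = levels[state]
            fl_next = k + (fl - k) * math.exp(-g * (t_next - t))
            new_side = fl_next >= theta
            if new_side != side:
                t_cross = t + math.log((fl - k) / (theta - k)) / g
                if side and not new_side:
                    n_down += 1
                    if settled:
                        above.append(t_cross - t_side)
                elif settled:
                    below.append(t_cross - t_side)
                side, t_side, settled = new_side, t_cross, True
            fl, t = fl_next, t_next
            if t >= t_end:
                break
            state = not state
        snap[i] = fl
    return snap, np.array(above), np.array(below), n_down / (n_cells * t_end)


def _dist_from_fluorescence(values):
    n = values.size
    table = fs.EventTable(fl1=np.clip(values, 1.0 + 1e-9, None),
                          fsc=np.full(n, 100.0), ssc=np.full(n, 80.0))
    return fs.smooth_histogram(fs.build_histogram(table))


@pytest.fixture(scope="module")
def oracle_run():
    """One well-resolved stationary run of the expression process."""
    snap, above, below, j_down = simulate_expression_process(
        r=0.05, f=0.02, g=G0, low_level=3.0, high_level=600.0, theta=50.0,
        n_cells=20_000, t_end=400.0, seed=11,
    )
    return snap, above, below, j_down


class TestDownwardCurrent:
    def test_zero_density_above_threshold(self):
        """No cells above the threshold means no downward flux."""
        values = np.full(5000, 5.0)
        dist = _dist_from_fluorescence(values)
        assert downward_current(dist, 1000.0, ORIGIN, NEUTRAL, G0) == 0.0

    def test_linearity_in_growth_rate(self, oracle_run):
        dist = _dist_from_fluorescence(oracle_run[0])
        i1 = downward_current(dist, 50.0, ORIGIN, NEUTRAL, G0)
        i2 = downward_current(dist, 50.0, ORIGIN, NEUTRAL, 2 * G0)
        assert i2 == pytest.approx(2 * i1, rel=1e-12)

    def test_matches_counted_crossings(self, oracle_run):
        """The dilution-flux formula reproduces directly counted downward
        threshold crossings within 15%."""
        snap, _, _, j_down = oracle_run
        dist = _dist_from_fluorescence(snap)
        i_down = downward_current(dist, 50.0, ORIGIN, NEUTRAL, G0)
        assert i_down / snap.size == pytest.approx(j_down, rel=0.15)

    def test_threshold_at_edge_rejected(self, oracle_run):
        dist = _dist_from_fluorescence(oracle_run[0])
        with pytest.raises(ValueError, match="edge"):
            downward_current(dist, dist.bin_centers[-1], ORIGIN, NEUTRAL, G0)


class TestFitnessCorrectedCurrents:
    def test_uniform_fitness_balances_currents(self, oracle_run):
        """Without fitness differences the upward and downward currents
        through any threshold cancel exactly."""
        dist = _dist_from_fluorescence(oracle_run[0])
        g_fn = lambda fc: np.full_like(fc, G0)
        est = fitness_corrected_currents(dist, 50.0, g_fn, G0, ORIGIN, NEUTRAL, G0)
        assert est.net == 0.0
        assert est.i_up == est.i_down

    def test_net_current_positive_when_low_state_fitter(self, oracle_run):
        """Fitter low expressors overproduce below the threshold; the surplus
        must flow upward in a stationary distribution."""
        dist = _dist_from_fluorescence(oracle_run[0])
        g_fn = lambda fc: G0 * (1.0 - 0.5 * fc / (fc + 100.0))  # decreasing in F
        dens = dist.probability(smoothed=True) / dist.bin_widths
        centers = dist.bin_centers
        g_t = float(np.trapezoid(g_fn(centers) * dens, centers)
                    / np.trapezoid(dens, centers))
        est = fitness_corrected_currents(dist, 50.0, g_fn, g_t, ORIGIN, NEUTRAL, G0)
        assert est.net > 0
        assert est.i_up > est.i_down

    def test_low_side_integral_equals_minus_high_side(self, oracle_run):
        """By stationarity the net production below theta equals the net
        deficit above it (same quadrature)."""
        dist = _dist_from_fluorescence(oracle_run[0])
        g_fn = lambda fc: G0 * (1.0 - 0.4 * fc / (fc + 200.0))
        centers = dist.bin_centers
        dens = dist.probability(smoothed=True) / dist.bin_widths
        g_t = float(np.trapezoid(g_fn(centers) * dens, centers)
                    / np.trapezoid(dens, centers))
        low = centers < 50.0
        net_low = np.trapezoid((g_fn(centers[low]) - g_t) * dens[low], centers[low])
        net_high = np.trapezoid((g_fn(centers[~low]) - g_t) * dens[~low], centers[~low])
        # the strip between the last low bin and first high bin is excluded
        # from both sides, so the cancellation holds to quadrature tolerance
        assert net_low + net_high == pytest.approx(0.0, abs=2e-3 * G0)

    def test_two_bin_hand_quadrature(self):
        """Hand-computed trapezoid on a tiny histogram."""
        edges = np.array([1.0, 10.0, 100.0, 1000.0])
        counts = np.array([60.0, 0.0, 40.0])
        dist = fs.FluorescenceDistribution(edges, counts, smoothed_counts=counts,
                                           smooth_window=1)
        centers = dist.bin_centers
        g_vals = np.array([0.3, 0.2, 0.1])
        g_fn = lambda fc: np.interp(fc, centers, g_vals)
        g_t = 0.2
        theta = 50.0
        dens = (counts / counts.sum()) / np.diff(edges)
        low = centers < theta
        expected_net = counts.sum() * np.trapezoid(
            (g_vals[low] - g_t) * dens[low], centers[low]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny histogram is not stationary
            est = fitness_corrected_currents(dist, theta, g_fn, g_t, ORIGIN, NEUTRAL, G0)
        assert est.net == pytest.approx(expected_net, rel=1e-12)

    def test_stationarity_violation_warns(self, oracle_run):
        dist = _dist_from_fluorescence(oracle_run[0])
        g_fn = lambda fc: np.full_like(fc, G0)
        with pytest.warns(UserWarning, match="stationarity"):
            fitness_corrected_currents(dist, 50.0, g_fn, 0.5 * G0, ORIGIN, NEUTRAL, G0)


class TestMemoryFromCurrents:
    def test_definition(self, oracle_run):
        dist = _dist_from_fluorescence(oracle_run[0])
        est = fs.CurrentEstimate(theta=50.0, i_down=1.0, i_up=2.0,
                                 n_low=200.0, n_high=100.0)
        mem = memory_from_currents(dist, est)
        assert mem.tau_high == 100.0
        assert mem.tau_low == 100.0

    def test_zero_current_flags_infinite_memory(self, oracle_run):
        dist = _dist_from_fluorescence(oracle_run[0])
        est = fs.CurrentEstimate(theta=50.0, i_down=0.0, i_up=0.0,
                                 n_low=10.0, n_high=10.0)
        mem = memory_from_currents(dist, est)
        assert math.isinf(mem.tau_high) and math.isinf(mem.tau_low)

    def test_memory_matches_first_passage_oracle(self, oracle_run):
        """Estimated residence times agree with directly measured mean
        sojourn times above/below the threshold within 20%."""
        snap, above, below, _ = oracle_run
        dist = _dist_from_fluorescence(snap)
        g_fn = lambda fc: np.full_like(fc, G0)
        est = fitness_corrected_currents(dist, 50.0, g_fn, G0, ORIGIN, NEUTRAL, G0)
        mem = memory_from_currents(dist, est)
        assert len(above) > 5000 and len(below) > 5000
        assert mem.tau_high == pytest.approx(above.mean(), rel=0.20)
        assert mem.tau_low == pytest.approx(below.mean(), rel=0.20)

    def test_memory_invariant_to_cell_number_scaling(self, oracle_run):
        dist = _dist_from_fluorescence(oracle_run[0])
        scaled = fs.FluorescenceDistribution(
            dist.bin_edges, dist.counts * 10.0,
            smoothed_counts=dist.smoothed_counts * 10.0,
            smooth_window=dist.smooth_window,
        )
        g_fn = lambda fc: np.full_like(fc, G0)
        mems = []
        for d in (dist, scaled):
            est = fitness_corrected_currents(d, 50.0, g_fn, G0, ORIGIN, NEUTRAL, G0)
            mems.append(memory_from_currents(d, est))
        assert mems[0].tau_high == pytest.approx(mems[1].tau_high, rel=1e-12)
        assert mems[0].tau_low == pytest.approx(mems[1].tau_low, rel=1e-12)


class TestMemoryDoseResponse:
    def test_identical_distributions_give_flat_memory(self, dose_dists):
        dists = {c: dose_dists[10.0] for c in (1.0, 2.0, 3.0)}
        table = fs.memory_dose_response(dists, ATcModelParams(alpha=0.0, g0=G0))
        assert table.tau_high.nunique() == 1
        assert table.tau_low.nunique() == 1

    def test_memory_trends_with_induction(self, memory_table):
        """Along the calibrated dose response the high-state memory rises
        and the low-state memory falls with the inducer."""
        sub = memory_table[memory_table.atc_ng_ml.isin([2.0, 4.0, 8.0, 16.0])]
        assert np.all(np.diff(sub.tau_high.to_numpy()) > 0)
        assert np.all(np.diff(sub.tau_low.to_numpy()) < 0)

    def test_memory_ratio_order_of_magnitude_at_balanced_induction(self, memory_table):
        """At balanced induction the high-state memory exceeds the low-state
        memory by more than an order of magnitude."""
        row = memory_table[memory_table.atc_ng_ml == 10.0].iloc[0]
        assert row.tau_high / row.tau_low > 10.0

    def test_estimates_track_simulator_ground_truth(self):
        """Across five switching-rate conditions the estimator stays within
        25% of the measured sojourn times.  Conditions are chosen so the
        true residence times are far shorter than the observation window;
        slower switching would censor the measured sojourns.
        """
        conditions = [(0.02, 0.05), (0.025, 0.04), (0.03, 0.03), (0.04, 0.025), (0.05, 0.02)]
        for i, (r, f) in enumerate(conditions):
            snap, above, below, _ = simulate_expression_process(
                r, f, G0, 3.0, 600.0, 50.0, n_cells=8000, t_end=400.0, seed=40 + i
            )
            dist = _dist_from_fluorescence(snap)
            g_fn = lambda fc: np.full_like(fc, G0)
            est = fitness_corrected_currents(dist, 50.0, g_fn, G0, ORIGIN, NEUTRAL, G0)
            mem = memory_from_currents(dist, est)
            assert mem.tau_high == pytest.approx(above.mean(), rel=0.25)
            assert mem.tau_low == pytest.approx(below.mean(), rel=0.25)

    def test_conservative_flag_set_when_smoothing_fills_empty_bins(self, dose_dists):
        table = fs.memory_dose_response({2.0: dose_dists[2.0]})
        assert bool(table.lower_bound.iloc[0])


class TestKernelSmooth:
    def test_fills_empty_bins_without_losing_mass(self):
        edges = np.logspace(0, 4, 257)
        counts = np.zeros(256)
        counts[[50, 51, 200]] = [100.0, 80.0, 60.0]
        dist = fs.FluorescenceDistribution(edges, counts)
        sm = kernel_smooth(dist, bandwidth_bins=2.0)
        assert sm.smoothed_counts.sum() == pytest.approx(counts.sum(), rel=1e-6)
        assert sm.smoothed_counts[49] > 0  # neighbouring empty bin filled
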