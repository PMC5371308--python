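"""Decision rules: fishing probability, thresholds, movement, return, memory."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marcpfs.agents import MemoryState
from marcpfs.behavior import (
    compute_th_t,
    crw_step,
    decide_departure,
    p_fishing,
    p_return,
    update_memory,
)


class TestPFishing:
    def test_half_at_threshold(self):
        assert p_fishing(4.0, th_t=4.0, is_night=True) == pytest.approx(0.5)

    def test_zero_by_day(self):
        assert p_fishing(10.0, 4.0, is_night=False) == 0.0

    def test_zero_below_profitability(self):
        assert p_fishing(1.4, 1.0, is_night=True) == 0.0

    def test_zero_at_satiety(self):
        assert p_fishing(10.0, 4.0, is_night=True, at_satiety=True) == 0.0

    def test_two_units_above_threshold(self):
        # expit(2 x 2) = e^4 / (1 + e^4)
        p = p_fishing(6.0, 4.0, is_night=True)
        assert p == pytest.approx(math.exp(4) / (1 + math.exp(4)), abs=1e-4)
        assert p == pytest.approx(0.9820, abs=1e-4)

    @settings(max_examples=60, deadline=None)
    @given(ab=st.floats(1.5, 30.0), th=st.floats(1.5, 15.0))
    def test_bounds_and_monotonicity(self, ab, th):
        p = p_fishing(ab, th, is_night=True)
        assert 0.0 <= p <= 1.0
        p_up = p_fishing(ab + 1.0, th, is_night=True)
        assert p_up > p or p_up == 1.0  # strictly increasing until saturation


class TestThreshold:
    def test_floor_at_lethal_limit(self):
        # a female at her lethal energy dives on anything profitable
        assert compute_th_t(10.0, e_ratio=1.0) == pytest.approx(1.5)

    def test_ceiling_at_full_reserves(self):
        # at the reserve ceiling only cells at least as rich as AvgEnv pay
        assert compute_th_t(10.0, e_ratio=1.0 / 0.7) == pytest.approx(10.0)

    def test_monotone_in_condition(self):
        assert compute_th_t(10.0, 1.3) > compute_th_t(10.0, 1.1)

    def test_units_conversion(self):
        # AvgEnv given in g/h: 366.67 g/h = 10 map units
        assert compute_th_t(1100 / 3, 1.0 / 0.7, units="g/h") == pytest.approx(10.0)


class TestCRW:
    def test_lag1_autocorrelation_near_observed(self):
        rng = np.random.default_rng(0)
        h = 0.0
        headings = []
        for _ in range(20000):
            h = crw_step(h, rng=rng)
            headings.append(h)
        headings = np.array(headings)
        lag1 = np.cos(np.diff(headings)).mean()
        lag5 = np.cos(headings[5:] - headings[:-5]).mean()
        assert 0.25 <= lag1 <= 0.35
        assert abs(lag5) < 0.05

    def test_zero_spread_is_straight_line(self):
        rng = np.random.default_rng(0)
        assert crw_step(1.0, rng=rng, sigma=0.0) == pytest.approx(1.0)

    def test_heading_wrapped(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            h = crw_step(3.0, rng=rng)
            assert -math.pi <= h <= math.pi


class TestPReturn:
    def test_boundary_cannot_afford_to_stay(self):
        assert p_return(e_frac=0.10, ewb_frac=0.10, ts_frac=0.1) == 1.0
        assert p_return(0.05, 0.10, 0.1) == 1.0

    def test_boundary_trip_ceiling(self):
        assert p_return(0.9, 0.1, 1.0) == 1.0

    def test_fresh_full_female_rarely_returns(self):
        assert p_return(0.95, 0.10, 0.05) < 0.05

    def test_monotonicity_scan(self):
        # non-increasing in e_frac, non-decreasing in ewb_frac and ts_frac
        es = np.linspace(0.3, 1.0, 10)
        ws = np.linspace(0.0, 0.25, 10)
        ts = np.linspace(0.0, 0.99, 10)
        for w in ws[::3]:
            for t in ts[::3]:
                p = [p_return(e, w, t) for e in es]
                assert all(a >= b - 1e-12 for a, b in zip(p, p[1:]))
        for e in es[::3]:
            for t in ts[::3]:
                p = [p_return(e, w, t) for w in ws]
                assert all(a <= b + 1e-12 for a, b in zip(p, p[1:]))
        for e in es[::3]:
            for w in ws[::3]:
                p = [p_return(e, w, t) for t in ts]
                assert all(a <= b + 1e-12 for a, b in zip(p, p[1:]))

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            p_return(-0.1, 0.1, 0.1)


class TestDeparture:
    def test_naive_female_leaves_at_default_hour(self):
        mem = MemoryState()
        assert decide_departure(17, mem, shore_hours=60.0) == "leave"
        assert decide_departure(12, mem, shore_hours=60.0) == "stay"

    def test_minimum_shore_stay(self):
        assert decide_departure(17, MemoryState(), shore_hours=2.0) == "stay"

    def test_departure_timed_to_reach_target_at_nightfall(self):
        # memorised cell 76 km away: 10 h travel; to arrive at the 22 h
        # nightfall she leaves around hour 12
        mem = MemoryState(best_cell=(505.0 + 76.0, 505.0), best_abundance=300.0)
        hours = [h for h in range(24)
                 if decide_departure(h, mem, 60.0, island_xy=(505.0, 505.0))
                 == "leave"]
        assert hours == [12]


class TestMemory:
    def test_richer_cell_becomes_reference(self):
        mem = MemoryState(best_cell=(100.0, 100.0), best_abundance=200.0)
        update_memory(mem, (150.0, 150.0), 300.0)
        assert mem.best_cell == (150.0, 150.0)

    def test_equal_cell_keeps_reference(self):
        mem = MemoryState(best_cell=(100.0, 100.0), best_abundance=200.0)
        update_memory(mem, (150.0, 150.0), 200.0)
        assert mem.best_cell == (100.0, 100.0)

    def test_fidelity_floor_after_failed_trip(self):
        mem = MemoryState(best_cell=(1.0, 1.0), best_abundance=10.0)
        update_memory(mem, (1.0, 1.0), 0.0, trip_summary=(0.0, 100.0))
        assert mem.fidelity == 0.0

    def test_fidelity_saturates_for_good_trips(self):
        mem = MemoryState()
        update_memory(mem, (1.0, 1.0), 10.0, trip_summary=(100.0, 100.0))
        assert 0.9 < mem.fidelity < 1.0
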