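"""Hourly decisions: fish vs move, movement kinematics, return, departure,
memory updating.

All probabilities are the jitted primitives of :mod:`._kernel`, exposed here
with their scientific contracts; the simulator's inner loop calls exactly the
same compiled code.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernel
from .agents import MemoryState
from .params import GRAMS_PER_UNIT, Params

_DEFAULT = Params()


def p_fishing(abundance: float, th_t: float, is_night: bool,
              at_satiety: bool = False, params: Params = _DEFAULT) -> float:
    """Probability of fishing the current cell this hour.

    Zero during the day (the prey is out of reach), below the profitability
    floor of 1.5 map units, or at satiety; otherwise the logistic
    expit(2 (abundance - th_t)), which is 0.5 exactly at the threshold.
    Abundance and th_t are in map units.
    """
    if abundance < 0:
        raise ValueError("abundance must be non-negative")
    if not is_night or at_satiety or abundance < params.min_fish_units:
        return 0.0
    return float(_kernel.p_fishing_logistic(abundance, th_t))


def compute_th_t(avg_env: float, e_ratio: float,
                 params: Params = _DEFAULT, units: str = "units") -> float:
    """Condition-dependent fishing threshold (map units).

    Interpolates between the profitability floor (a female at her lethal
    limit dives on anything worth the effort) and AvgEnv (a female with full
    stores only bothers with cells at least as rich as the non-zero-
    environment mean).  ``e_ratio`` is E_seal / E_min.
    """
    avg_u = avg_env / GRAMS_PER_UNIT if units == "g/h" else avg_env
    return float(_kernel.compute_th_t(avg_u, e_ratio, params.min_fish_units,
                                      params.lethal_frac_female))


def crw_step(heading: float, rng=None, sigma: float | None = None,
             params: Params = _DEFAULT) -> float:
    """One correlated-random-walk heading update (radians).

    The turning angle is wrapped-normal with sd calibrated so the lag-1
    autocorrelation of successive headings is ~0.30 (sd -> 0 gives straight-
    line travel; sd -> infinity a pure random walk).
    """
    sigma = params.crw_sigma if sigma is None else sigma
    rng = np.random.default_rng() if rng is None else rng
    turn = rng.normal(0.0, sigma)
    return float(_kernel._wrap_angle(heading + turn))


def p_return(e_frac: float, ewb_frac: float, ts_frac: float,
             params: Params = _DEFAULT) -> float:
    """Probability of deciding to head home (per night hour at sea).

    Non-increasing in the energy fraction e_frac = E_seal/E_max,
    non-decreasing in the return-cost fraction ewb_frac = E_wb/E_max and in
    the trip clock ts_frac = ts/T_max; exactly 1 when the stores no longer
    cover the trip home or the trip ceiling is reached.
    """
    if min(e_frac, ewb_frac, ts_frac) < 0:
        raise ValueError("fractions must be non-negative")
    return float(_kernel.p_return(e_frac, ewb_frac, ts_frac, params.ret_k,
                                  params.ret_x0, params.ret_ramp_coeff,
                                  params.ret_ramp_pow))


def choose_heading(position, memory: MemoryState | None, mode: str,
                   rng=None, gradient_to=None, params: Params = _DEFAULT) -> float:
    """Heading for the next movement hour.

    ``mode='transit'`` heads straight for the memorised best cell;
    ``mode='search'`` is a CRW step biased by the last sensed abundance
    gradient (``gradient_to`` = bearing of improvement, or None);
    ``mode='naive'`` draws a uniform heading (first prenatal hour).
    """
    rng = np.random.default_rng() if rng is None else rng
    if mode == "transit":
        if memory is None or memory.best_cell is None:
            raise ValueError("transit mode requires a memorised cell")
        bx, by = memory.best_cell
        return math.atan2(by - position[1], bx - position[0])
    if mode == "naive":
        return float(rng.uniform(0.0, 2.0 * math.pi))
    base = gradient_to if gradient_to is not None else position[2]
    return crw_step(base, rng=rng, params=params)


def decide_departure(hour_of_day: int, memory: MemoryState | None,
                     shore_hours: float, island_xy=None,
                     params: Params = _DEFAULT) -> str:
    """'leave' or 'stay' for a female ashore at the given hour.

    Departure is timed so that a Mem1 female travelling straight reaches her
    memorised cell at nightfall; without a target she leaves at the colony's
    typical departure hour (17 h).  Nobody leaves before the minimum shore
    stay.
    """
    if shore_hours < params.min_shore_h:
        return "stay"
    has_target = (memory is not None and memory.best_cell is not None)
    if has_target:
        ox, oy = island_xy if island_xy is not None else (505.0, 505.0)
        tdist = math.hypot(memory.best_cell[0] - ox, memory.best_cell[1] - oy)
    else:
        tdist = 0.0
    dep = _kernel._departure_hour(has_target, tdist, params.v_kmh,
                                  params.departure_hour, params.night_start)
    return "leave" if hour_of_day == int(dep) else "stay"


def update_memory(memory: MemoryState, cell, abundance: float,
                  trip_summary=None, params: Params = _DEFAULT) -> MemoryState:
    """Replace the reference cell iff strictly richer; at trip end set the
    fidelity from the realised gain rate g = E_won / duration."""
    if abundance > memory.best_abundance:
        memory.best_cell = tuple(cell)
        memory.best_abundance = abundance
    if trip_summary is not None:
        e_won, duration = trip_summary
        g = e_won / duration if duration > 0 else 0.0
        memory.last_trip_gain_rate = g
        memory.fidelity = g / (g + params.g_half)
    return memory
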