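"""Compiled hourly core of the central-place-forager simulation.

All per-hour arithmetic lives here as numba ``njit`` functions so that a full
rearing season (~3,400 hourly steps) runs in well under a millisecond and the
factorial experiment layer can execute thousands of seasons on one CPU.  The
public modules (:mod:`behavior`, :mod:`energetics`, :mod:`mortality`,
:mod:`scheduler`) expose these same primitives, so the code unit tests exercise
is the code the simulator runs.

State is a flat float64 vector with the ``S_*`` indices below; the parameter
vector layout is defined in :mod:`.params`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import (
    P_CELL_KM,
    P_CRW_SIGMA,
    P_CRW_SIGMA_SEARCH,
    P_START_HOUR,
    P_D_MAX,
    P_DEP_HOUR,
    P_DRAG_COEFF,
    P_ECONT_PUP,
    P_ECONT_SEAL,
    P_EMAX_FACTOR,
    P_FMR,
    P_G_HALF,
    P_ORBIT_FRAC,
    P_MEM_LAMBDA,
    P_NAV_ERR,
    P_GRAMS_PER_UNIT,
    P_KCAL_PER_G,
    P_KJ_PER_KCAL,
    P_LENGTH,
    P_LETHAL_F,
    P_LETHAL_P,
    P_MAX_SHORE,
    P_MEM,
    P_MILK_EFF,
    P_MIN_FISH_U,
    P_MIN_SHORE,
    P_MORT_SD,
    P_NIGHT_END,
    P_NIGHT_START,
    P_PERI_GAIN,
    P_PERI_MAX_D,
    P_PERI_MIN_D,
    P_PRENATAL_H,
    P_PUP_LOSS,
    P_R_MILK,
    P_MILK_FLOOR,
    P_RET_K,
    P_RET_RAMP_C,
    P_RET_RAMP_P,
    P_FULL_FRAC,
    P_SAT_MARGIN,
    P_MIN_TRIP_H,
    P_RET_X0,
    P_SAT_FRAC,
    P_SHORE_FACTOR,
    P_T_MAX_TRIP,
    P_T_REAR,
    P_V_KMH,
    P_W_INITPUP,
    P_W_MAXPUP,
)

# ---------------------------------------------------------------------------
# state-vector layout
# ---------------------------------------------------------------------------
(
    S_T,            # absolute hour since simulation start
    S_PHASE,        # 0 prenatal / 1 perinatal / 2 rearing / 3 finished
    S_TREAR,        # hours into the rearing phase
    S_X,            # km, map frame
    S_Y,
    S_HEADING,      # radians
    S_ESEAL,        # MJ
    S_EINIT,        # female mortality reference energy (<= S_EINIT0)
    S_EINIT0,       # energy at initialisation (milk floor anchor)
    S_EMAX,
    S_EMIN,
    S_EFN,          # energy at dawn = end of former night
    S_ATSEA,
    S_RETURNING,
    S_TRANSIT,
    S_TS,           # hours at sea this trip
    S_TSHORE,       # hours ashore this visit
    S_TSUCKLING,    # suckling hours this visit
    S_EPUP,
    S_REFPUP,       # pup reference energy (after last suckling bout)
    S_FALIVE,
    S_PALIVE,
    S_BORN,
    S_BESTX,        # memorised best cell centre, km
    S_BESTY,
    S_BESTAB,       # its abundance, g h^-1
    S_BESTSCORE,    # its distance-discounted score
    S_TGTX,         # transit waypoint: memorised cell + navigation scatter
    S_TGTY,
    S_FIDELITY,
    S_PREVAB,       # abundance of previous distinct cell (gradient sensing)
    S_CURAB,
    S_CURCI,
    S_CURCJ,
    S_GRADBIAS,     # pending turning bias (0 or pi)
    S_TRIP_D,       # current-trip accumulators
    S_TRIP_FISH,
    S_TRIP_EWON,
    S_TRIP_T0,
    S_NTRIP,        # rearing-phase totals
    S_SUM_TD,
    S_SUM_TH,
    S_NFISH,
    S_ESPENT,       # total female energy expenditure during rearing
    S_PERI_END,     # absolute hour at which the perinatal fast ends
    S_PERI_DUR,     # perinatal fast duration, h
    S_SUCKLED,      # pup attended this hour
    S_H_GAIN,       # per-hour ledger entries (reset every step)
    S_H_METAB,
    S_H_DRAG,
    S_H_TRANSFER,
    S_LAST_TD,      # last completed trip (for logging)
    S_LAST_TS,
    S_LAST_FISH,
    S_LAST_EWON,
    S_LAST_T0,
) = range(56)
N_STATE = 56

# event bits returned by _step
EV_TRIP_START = 1
EV_TRIP_END = 2
EV_FISHED = 4
EV_FEMALE_DEATH = 8
EV_PUP_DEATH = 16
EV_BIRTH = 32

TWO_PI = 2.0 * math.pi
SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# elementary model functions
# ---------------------------------------------------------------------------
@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def norm_cdf(z):
    return 0.5 * (1.0 + math.erf(z / SQRT2))


@njit(cache=True)
def p_fishing_logistic(abundance_units, th_t):
    """P(fishing) = expit(2 (abundance - th_t)); gating handled by callers."""
    return 1.0 / (1.0 + math.exp(-2.0 * (abundance_units - th_t)))


@njit(cache=True)
def compute_th_t(avg_env_units, e_ratio, min_fish_units, lethal_frac):
    """Fishing threshold between the profitability floor and AvgEnv.

    e_ratio = E_seal / E_min runs from 1 (at the lethal limit: fish anywhere
    profitable) to 1/lethal_frac (energy at its reference level: only cells at
    least as rich as the non-zero-environment mean are worth a dive).
    """
    ceiling = 1.0 / lethal_frac
    f = (e_ratio - 1.0) / (ceiling - 1.0)
    if f < 0.0:
        f = 0.0
    elif f > 1.0:
        f = 1.0
    hi = avg_env_units
    if hi < min_fish_units:
        hi = min_fish_units
    return min_fish_units + (hi - min_fish_units) * f


@njit(cache=True)
def p_return(e_frac, ewb_frac, ts_frac, k, x0, ramp_c, ramp_p):
    """Probability of deciding to head home, evaluated once per night hour.

    Logistic in the energy margin x = e_frac - ewb_frac (how much of the
    current stores exceed the cost of getting home plus two days ashore) with
    an additive ramp in the trip clock; clamps to 1 when the margin is gone or
    the trip ceiling is reached.
    """
    x = e_frac - ewb_frac
    if x <= 0.0 or ts_frac >= 1.0:
        return 1.0
    p = 1.0 / (1.0 + math.exp(k * (x - x0))) + ramp_c * ts_frac**ramp_p
    if p > 1.0:
        p = 1.0
    return p


@njit(cache=True)
def p_death_probit(current_energy, reference_energy, lethal_frac, sd_pct):
    """Hourly death probability: Phi centred at the lethal percentage."""
    pct = 100.0 * current_energy / reference_energy
    return norm_cdf((100.0 * lethal_frac - pct) / sd_pct)


@njit(cache=True)
def drag_per_km(length_cm, drag_coeff):
    """Displacement cost in MJ km^-1; quadratic in body length."""
    return drag_coeff * length_cm * length_cm


@njit(cache=True)
def fishing_gain(abundance_gh, e_seal, e_max, e_fn, sat_frac, kcal_per_g, kj_per_kcal):
    """Energy won in one fishing hour after satiation and the E_max ceiling."""
    gain = abundance_gh * kcal_per_g * kj_per_kcal * 1e-3
    cap = sat_frac * e_fn
    if gain > cap:
        gain = cap
    room = e_max - e_seal
    if room < 0.0:
        room = 0.0
    if gain > room:
        gain = room
    if gain < 0.0:
        gain = 0.0
    return gain


@njit(cache=True)
def crw_turn(sigma):
    """Zero-mean wrapped-normal turning angle."""
    return np.random.normal(0.0, sigma)


@njit(cache=True)
def _wrap_angle(a):
    while a > math.pi:
        a -= TWO_PI
    while a < -math.pi:
        a += TWO_PI
    return a


@njit(cache=True)
def _is_night(hod, night_start, night_end):
    return hod >= night_start or hod < night_end


@njit(cache=True)
def _departure_hour(has_target, target_dist, v_kmh, dep_default, night_start):
    """Shore-departure hour: timed so a directed traveller reaches the target
    at nightfall; naive females use the default colony departure hour."""
    if not has_target:
        return dep_default
    tau = target_dist / v_kmh
    h = int(round(night_start - tau)) % 24
    return h


@njit(cache=True)
def _set_transit_target(s, from_x, from_y, nav_err):
    """Aim for the memorised cell with navigation scatter growing with the
    distance to cover: small patches are hard to relocate from afar."""
    d = math.hypot(s[S_BESTX] - from_x, s[S_BESTY] - from_y)
    sd = nav_err * d
    s[S_TGTX] = s[S_BESTX] + np.random.normal(0.0, sd)
    s[S_TGTY] = s[S_BESTY] + np.random.normal(0.0, sd)
    s[S_TRANSIT] = 1.0


# ---------------------------------------------------------------------------
# state initialisation
# ---------------------------------------------------------------------------
@njit(cache=True)
def init_state(p, island_x, island_y):
    """Fresh state at the start of the prenatal prospection (female at sea,
    random naive heading, first trip open)."""
    s = np.zeros(N_STATE, dtype=np.float64)
    length = p[P_LENGTH]
    w_init = 0.5246 * length - 29.595
    e_init = w_init * p[P_ECONT_SEAL]
    s[S_X] = island_x
    s[S_Y] = island_y
    s[S_HEADING] = np.random.uniform(0.0, TWO_PI)
    s[S_ESEAL] = e_init
    s[S_EINIT] = e_init
    s[S_EINIT0] = e_init
    s[S_EMAX] = p[P_EMAX_FACTOR] * e_init
    s[S_EMIN] = p[P_LETHAL_F] * e_init
    s[S_EFN] = e_init
    s[S_ATSEA] = 1.0
    s[S_FALIVE] = 1.0
    s[S_FIDELITY] = 0.0
    s[S_CURCI] = -1.0
    s[S_CURCJ] = -1.0
    s[S_TRIP_T0] = 0.0
    peri_days = p[P_PERI_MIN_D] + np.floor(
        np.random.random() * (p[P_PERI_MAX_D] - p[P_PERI_MIN_D] + 1.0)
    )
    s[S_PERI_DUR] = 24.0 * peri_days
    return s


# ---------------------------------------------------------------------------
# one hour of simulation
# ---------------------------------------------------------------------------
@njit(cache=True)
def _step(s, grid, avg_env_gh, island_x, island_y, p, fishmap):
    """Advance the simulation by one hour.  Mutates ``s`` in place and returns
    an event bitmask.  Exactly one flow-chart branch executes per call."""
    ev = 0
    t = s[S_T]
    hod = (int(t) + int(p[P_START_HOUR])) % 24
    night = _is_night(hod, int(p[P_NIGHT_START]), int(p[P_NIGHT_END]))
    phase = int(s[S_PHASE])
    cell = p[P_CELL_KM]
    gpu = p[P_GRAMS_PER_UNIT]
    econt = p[P_ECONT_SEAL]
    v_kmh = p[P_V_KMH]
    rearing = phase == 2

    s[S_H_GAIN] = 0.0
    s[S_H_METAB] = 0.0
    s[S_H_DRAG] = 0.0
    s[S_H_TRANSFER] = 0.0
    s[S_SUCKLED] = 0.0

    falive = s[S_FALIVE] > 0.5

    # dawn: the former night just ended; reset the satiation reference.
    # E_max itself is the fixed ceiling 1.07 x the initial mass in energy
    # terms, set at initialisation.
    if falive and hod == int(p[P_NIGHT_END]):
        s[S_EFN] = s[S_ESEAL]

    if falive:
        w = s[S_ESEAL] / econt
        e_mh = p[P_FMR] * w
        if s[S_ATSEA] > 0.5:
            # ----------------------------------------------------- at sea
            s[S_TS] += 1.0
            dx = island_x - s[S_X]
            dy = island_y - s[S_Y]
            d_isl = math.hypot(dx, dy)
            dragk = drag_per_km(p[P_LENGTH], p[P_DRAG_COEFF])
            # trip-length clocks scale with storage capacity: bigger females
            # carry bigger loads on fewer, longer trips
            mr = (0.5246 * p[P_LENGTH] - 29.595) / 30.734
            tmax_eff = p[P_T_MAX_TRIP] * mr
            mintrip_eff = p[P_MIN_TRIP_H] * mr
            tau_home = d_isl / v_kmh
            # energy needed to go back: travel home plus two days ashore
            e_wb = tau_home * (e_mh + v_kmh * dragk) + 48.0 * p[P_SHORE_FACTOR] * e_mh

            # prenatal: head home in time for the birth
            if phase == 0 and t >= p[P_PRENATAL_H] - (tau_home + 2.0):
                s[S_RETURNING] = 1.0

            if s[S_RETURNING] < 0.5 and (
                s[S_TS] >= tmax_eff or s[S_ESEAL] <= e_wb
            ):
                s[S_RETURNING] = 1.0

            # load complete: a female still near satiety when the night ends
            # has nothing more to gain at sea
            if (
                s[S_RETURNING] < 0.5
                and hod == int(p[P_NIGHT_END])
                and s[S_TS] >= mintrip_eff
                and s[S_ESEAL] >= p[P_FULL_FRAC] * s[S_EMAX]
            ):
                s[S_RETURNING] = 1.0

            if s[S_RETURNING] < 0.5 and night:
                pr = p_return(
                    s[S_ESEAL] / s[S_EMAX],
                    e_wb / s[S_EMAX],
                    s[S_TS] / tmax_eff,
                    p[P_RET_K],
                    p[P_RET_X0],
                    p[P_RET_RAMP_C],
                    p[P_RET_RAMP_P],
                )
                if np.random.random() < pr:
                    s[S_RETURNING] = 1.0

            ci = int(s[S_X] / cell)
            cj = int(s[S_Y] / cell)
            if ci < 0:
                ci = 0
            elif ci > 99:
                ci = 99
            if cj < 0:
                cj = 0
            elif cj > 99:
                cj = 99

            # a female travelling directly to her memorised area does not
            # interrupt the transit to fish en route
            if (
                s[S_TRANSIT] > 0.5
                and p[P_MEM] > 0.5
                and s[S_BESTAB] > 0.0
                and grid[ci, cj] >= p[P_ORBIT_FRAC] * s[S_BESTAB]
            ):
                s[S_TRANSIT] = 0.0  # good-enough water reached
            fished = False
            if night and s[S_RETURNING] < 0.5:
                ab_gh = grid[ci, cj]
                ab_u = ab_gh / gpu
                if ab_u >= p[P_MIN_FISH_U] and s[S_ESEAL] < s[S_EMAX] - p[P_SAT_MARGIN]:
                    th = compute_th_t(
                        avg_env_gh / gpu,
                        s[S_ESEAL] / s[S_EMIN],
                        p[P_MIN_FISH_U],
                        p[P_LETHAL_F],
                    )
                    if np.random.random() < p_fishing_logistic(ab_u, th):
                        fished = True

            if fished:
                gain = fishing_gain(
                    grid[ci, cj],
                    s[S_ESEAL],
                    s[S_EMAX],
                    s[S_EFN],
                    p[P_SAT_FRAC],
                    p[P_KCAL_PER_G],
                    p[P_KJ_PER_KCAL],
                )
                s[S_ESEAL] += gain - e_mh
                s[S_H_GAIN] = gain
                s[S_H_METAB] = e_mh
                s[S_TRIP_EWON] += gain
                s[S_TRIP_FISH] += 1.0
                if rearing:
                    s[S_NFISH] += 1.0
                    s[S_ESPENT] += e_mh
                    fishmap[ci, cj] += 1.0
                ev |= EV_FISHED
            else:
                # choose a heading, then move one hour at constant speed
                if s[S_RETURNING] > 0.5:
                    s[S_HEADING] = math.atan2(dy, dx)
                elif s[S_TRANSIT] > 0.5:
                    bx = s[S_TGTX] - s[S_X]
                    by = s[S_TGTY] - s[S_Y]
                    if math.hypot(bx, by) <= v_kmh:
                        s[S_TRANSIT] = 0.0  # reached where she believes it is
                    s[S_HEADING] = math.atan2(by, bx)
                elif (
                    p[P_MEM] > 0.5
                    and s[S_BESTAB] > 0.0
                    and not (phase == 0 and t < 0.3 * p[P_PRENATAL_H])
                    and grid[ci, cj] < p[P_ORBIT_FRAC] * s[S_BESTAB]
                    and math.hypot(s[S_BESTX] - s[S_X], s[S_BESTY] - s[S_Y]) > v_kmh
                ):
                    # on clearly poorer water: head back to the memorised area
                    _set_transit_target(s, s[S_X], s[S_Y], p[P_NAV_ERR])
                    s[S_HEADING] = math.atan2(s[S_TGTY] - s[S_Y],
                                              s[S_TGTX] - s[S_X])
                else:
                    if d_isl >= p[P_D_MAX]:
                        # outside the resource disc: bend back toward it
                        s[S_HEADING] = math.atan2(dy, dx) + crw_turn(p[P_CRW_SIGMA])
                    else:
                        # CRW forages within food-bearing zones; unprofitable
                        # water (plateau, gaps, the poor inner belt) is
                        # crossed near-straight
                        profitable = s[S_CURAB] >= p[P_MIN_FISH_U] * p[P_GRAMS_PER_UNIT]
                        sig = p[P_CRW_SIGMA] if profitable else p[P_CRW_SIGMA_SEARCH]
                        s[S_HEADING] = _wrap_angle(
                            s[S_HEADING] + s[S_GRADBIAS] + crw_turn(sig)
                        )
                    s[S_GRADBIAS] = 0.0

                arrived = False
                if s[S_RETURNING] > 0.5 and d_isl <= v_kmh:
                    step_km = d_isl
                    s[S_X] = island_x
                    s[S_Y] = island_y
                    arrived = True
                else:
                    s[S_X] += v_kmh * math.cos(s[S_HEADING])
                    s[S_Y] += v_kmh * math.sin(s[S_HEADING])
                    # reflect at the map border
                    lim = 100.0 * cell
                    if s[S_X] < 0.0:
                        s[S_X] = -s[S_X]
                    elif s[S_X] > lim:
                        s[S_X] = 2.0 * lim - s[S_X]
                    if s[S_Y] < 0.0:
                        s[S_Y] = -s[S_Y]
                    elif s[S_Y] > lim:
                        s[S_Y] = 2.0 * lim - s[S_Y]
                    step_km = v_kmh

                drag_cost = dragk * step_km
                s[S_ESEAL] -= e_mh + drag_cost
                s[S_H_METAB] = e_mh
                s[S_H_DRAG] = drag_cost
                s[S_TRIP_D] += step_km
                if rearing:
                    s[S_ESPENT] += e_mh + drag_cost

                if arrived:
                    s[S_ATSEA] = 0.0
                    s[S_RETURNING] = 0.0
                    s[S_TRANSIT] = 0.0
                    s[S_TSHORE] = 0.0
                    s[S_TSUCKLING] = 0.0
                    dur = s[S_TS]
                    g = s[S_TRIP_EWON] / dur if dur > 0.0 else 0.0
                    s[S_FIDELITY] = g / (g + p[P_G_HALF])
                    s[S_LAST_TD] = s[S_TRIP_D]
                    s[S_LAST_TS] = dur
                    s[S_LAST_FISH] = s[S_TRIP_FISH]
                    s[S_LAST_EWON] = s[S_TRIP_EWON]
                    s[S_LAST_T0] = s[S_TRIP_T0]
                    if rearing:
                        s[S_NTRIP] += 1.0
                        s[S_SUM_TD] += s[S_TRIP_D]
                        s[S_SUM_TH] += dur
                    ev |= EV_TRIP_END
                else:
                    nci = int(s[S_X] / cell)
                    ncj = int(s[S_Y] / cell)
                    if nci < 0:
                        nci = 0
                    elif nci > 99:
                        nci = 99
                    if ncj < 0:
                        ncj = 0
                    elif ncj > 99:
                        ncj = 99
                    if nci != int(s[S_CURCI]) or ncj != int(s[S_CURCJ]):
                        newab = grid[nci, ncj]
                        if s[S_CURCI] >= 0.0:
                            # gradient between the last two visited cells
                            if newab < s[S_CURAB] - 1e-12:
                                s[S_GRADBIAS] = math.pi
                            else:
                                s[S_GRADBIAS] = 0.0
                        s[S_PREVAB] = s[S_CURAB]
                        s[S_CURAB] = newab
                        s[S_CURCI] = float(nci)
                        s[S_CURCJ] = float(ncj)
                        if p[P_MEM] > 0.5:
                            # rich cells near the colony are preferred to
                            # equally rich distant ones
                            cx = (nci + 0.5) * cell
                            cy = (ncj + 0.5) * cell
                            dc = math.hypot(cx - island_x, cy - island_y)
                            score = newab * math.exp(-dc / p[P_MEM_LAMBDA])
                            if score > s[S_BESTSCORE]:
                                s[S_BESTSCORE] = score
                                s[S_BESTAB] = newab
                                s[S_BESTX] = cx
                                s[S_BESTY] = cy
        else:
            # ----------------------------------------------------- ashore
            cost = p[P_SHORE_FACTOR] * e_mh
            s[S_ESEAL] -= cost
            s[S_H_METAB] = cost
            if rearing:
                s[S_ESPENT] += cost

            if phase == 1:
                # perinatal fast: transfer the fixed perinatal gain linearly
                rate = p[P_PERI_GAIN] * p[P_ECONT_PUP] / max(s[S_PERI_DUR], 1.0)
                tr = min(rate, s[S_ESEAL])
                s[S_ESEAL] -= tr
                s[S_EPUP] += tr * p[P_MILK_EFF]
                s[S_H_TRANSFER] = tr
                s[S_SUCKLED] = 1.0
                s[S_TSUCKLING] += 1.0
            elif rearing:
                if s[S_BORN] > 0.5 and s[S_PALIVE] > 0.5:
                    # milk comes from the tranche above the donation floor: a
                    # depleted mother protects her own reserve first
                    surplus = s[S_ESEAL] - p[P_MILK_FLOOR] * s[S_EINIT0]
                    if surplus > 0.0:
                        tr = p[P_R_MILK] * surplus
                        room = (
                            p[P_W_MAXPUP] * p[P_ECONT_PUP] - s[S_EPUP]
                        ) / p[P_MILK_EFF]
                        if room < 0.0:
                            room = 0.0
                        if tr > room:
                            tr = room
                        if tr > s[S_ESEAL]:
                            tr = s[S_ESEAL]
                        s[S_ESEAL] -= tr
                        s[S_EPUP] += tr * p[P_MILK_EFF]
                        s[S_H_TRANSFER] = tr
                        if rearing:
                            s[S_ESPENT] += tr
                    s[S_SUCKLED] = 1.0
                    s[S_TSUCKLING] += 1.0
                s[S_TSHORE] += 1.0
                # departure decision
                has_target = p[P_MEM] > 0.5 and s[S_BESTAB] > 0.0
                tdist = math.hypot(s[S_BESTX] - island_x, s[S_BESTY] - island_y)
                dep = _departure_hour(
                    has_target, tdist, v_kmh, int(p[P_DEP_HOUR]), int(p[P_NIGHT_START])
                )
                if s[S_TSHORE] >= p[P_MIN_SHORE] and hod == dep:
                    ev |= _depart(s, p, island_x, island_y)
            else:
                # prenatal shore visit
                s[S_TSHORE] += 1.0
                if s[S_TSHORE] >= p[P_MIN_SHORE] and hod == int(p[P_DEP_HOUR]):
                    # the approaching birth itself recalls her in time (the
                    # forced return below), so she may leave until late
                    if t < p[P_PRENATAL_H] - 24.0:
                        ev |= _depart(s, p, island_x, island_y)

        if s[S_ESEAL] < 0.0:
            s[S_ESEAL] = 0.0
        # hourly mortality draw; starvation risk is evaluated from birth
        # onwards (the prenatal prospection precedes the simulated season)
        if phase >= 1:
            pd = p_death_probit(s[S_ESEAL], s[S_EINIT], p[P_LETHAL_F], p[P_MORT_SD])
            if np.random.random() < pd:
                s[S_FALIVE] = 0.0
                ev |= EV_FEMALE_DEATH

    # --------------------------------------------------------------- pup
    if s[S_BORN] > 0.5 and s[S_PALIVE] > 0.5:
        if s[S_SUCKLED] < 0.5 and phase == 2:
            # fasting cost cannot fall below the structural (post-perinatal)
            # level: an underfed pup keeps burning like a healthy newborn
            floor = (p[P_W_INITPUP] + p[P_PERI_GAIN]) * p[P_ECONT_PUP]
            basis = s[S_EPUP] if s[S_EPUP] > floor else floor
            s[S_EPUP] -= p[P_PUP_LOSS] * basis
            if s[S_EPUP] < 0.0:
                s[S_EPUP] = 0.0
        pd = p_death_probit(s[S_EPUP], s[S_REFPUP], p[P_LETHAL_P], p[P_MORT_SD])
        if np.random.random() < pd:
            s[S_PALIVE] = 0.0
            ev |= EV_PUP_DEATH

    # ------------------------------------------------------- phase clock
    s[S_T] = t + 1.0
    if phase == 0:
        if s[S_FALIVE] < 0.5:
            s[S_PHASE] = 3.0  # no birth; pup never exists
        elif s[S_T] >= p[P_PRENATAL_H] and s[S_ATSEA] < 0.5:
            # birth; the prospection ends here, so the female's mortality
            # reference is taken at this point too
            ref = s[S_ESEAL] if s[S_ESEAL] < s[S_EINIT0] else s[S_EINIT0]
            s[S_EINIT] = ref
            s[S_EMIN] = p[P_LETHAL_F] * ref
            s[S_PHASE] = 1.0
            s[S_PERI_END] = s[S_T] + s[S_PERI_DUR]
            s[S_EPUP] = p[P_W_INITPUP] * p[P_ECONT_PUP]
            s[S_REFPUP] = s[S_EPUP]
            s[S_BORN] = 1.0
            s[S_PALIVE] = 1.0
            ev |= EV_BIRTH
    elif phase == 1:
        if s[S_T] >= s[S_PERI_END]:
            s[S_PHASE] = 2.0
            s[S_TREAR] = 0.0
            if s[S_EPUP] > s[S_REFPUP]:
                s[S_REFPUP] = s[S_EPUP]  # end of the perinatal suckling bout
            s[S_TSHORE] = p[P_MIN_SHORE]  # free to leave at the next window
        if s[S_FALIVE] < 0.5 and s[S_PALIVE] < 0.5:
            s[S_PHASE] = 3.0
    elif phase == 2:
        s[S_TREAR] += 1.0
        if s[S_TREAR] >= p[P_T_REAR]:
            s[S_PHASE] = 3.0
        if s[S_FALIVE] < 0.5 and s[S_PALIVE] < 0.5:
            s[S_PHASE] = 3.0
    return ev


@njit(cache=True)
def _depart(s, p, island_x, island_y):
    """Leave the island: open a new trip, pick transit vs naive search."""
    s[S_ATSEA] = 1.0
    s[S_TS] = 0.0
    s[S_TRIP_D] = 0.0
    s[S_TRIP_FISH] = 0.0
    s[S_TRIP_EWON] = 0.0
    s[S_TRIP_T0] = s[S_T]
    s[S_RETURNING] = 0.0
    s[S_GRADBIAS] = 0.0
    # a depleted female defends a lowered reference (the mass at the end of
    # the last shore period), never above her initial level
    ref = s[S_ESEAL] if s[S_ESEAL] < s[S_EINIT0] else s[S_EINIT0]
    s[S_EINIT] = ref
    s[S_EMIN] = p[P_LETHAL_F] * ref
    s[S_CURCI] = -1.0
    s[S_CURCJ] = -1.0
    s[S_CURAB] = 0.0
    s[S_PREVAB] = 0.0
    if s[S_BORN] > 0.5 and s[S_EPUP] > s[S_REFPUP]:
        # the pup's mortality reference is its best-fed post-suckling state;
        # chronic underfeeding therefore accumulates across trips
        s[S_REFPUP] = s[S_EPUP]
    exploring = s[S_PHASE] < 0.5 and s[S_T] < 0.3 * p[P_PRENATAL_H]
    if (
        p[P_MEM] > 0.5
        and s[S_BESTAB] > 0.0
        and not exploring
        and np.random.random() < s[S_FIDELITY]
    ):
        _set_transit_target(s, island_x, island_y, p[P_NAV_ERR])
        s[S_HEADING] = math.atan2(s[S_TGTY] - island_y, s[S_TGTX] - island_x)
    else:
        s[S_TRANSIT] = 0.0
        s[S_HEADING] = np.random.uniform(0.0, TWO_PI)
    return EV_TRIP_START


# maximum simulated hours: prenatal + slack + perinatal + rearing
MAX_HOURS = 360 + 240 + 7 * 24 + 2880 + 2
MAX_TRIPS = 400
TRACE_COLS = 15


@njit(cache=True)
def run_core(grid, avg_env_gh, island_x, island_y, p, seed, fishmap, trace, do_trace):
    """Run one full simulation (prenatal + perinatal + rearing).

    Returns (state, trips[:n, 5], n_trips_logged, hours_run).  Trip rows are
    (t_start, t_end, distance_km, n_fishing, e_won) for rearing-phase trips.
    ``fishmap`` accumulates rearing-phase fishing events per cell in place.
    """
    np.random.seed(seed)
    s = init_state(p, island_x, island_y)
    trips = np.zeros((MAX_TRIPS, 5), dtype=np.float64)
    ntr = 0
    h = 0
    while h < MAX_HOURS and s[S_PHASE] < 2.5:
        rearing_before = int(s[S_PHASE]) == 2
        ev = _step(s, grid, avg_env_gh, island_x, island_y, p, fishmap)
        if (ev & EV_TRIP_END) != 0 and rearing_before and ntr < MAX_TRIPS:
            trips[ntr, 0] = s[S_LAST_T0]
            trips[ntr, 1] = s[S_LAST_T0] + s[S_LAST_TS]
            trips[ntr, 2] = s[S_LAST_TD]
            trips[ntr, 3] = s[S_LAST_FISH]
            trips[ntr, 4] = s[S_LAST_EWON]
            ntr += 1
        if do_trace and h < trace.shape[0]:
            trace[h, 0] = s[S_T] - 1.0
            trace[h, 1] = s[S_PHASE]
            trace[h, 2] = s[S_ATSEA]
            trace[h, 3] = s[S_X]
            trace[h, 4] = s[S_Y]
            trace[h, 5] = s[S_ESEAL]
            trace[h, 6] = s[S_EPUP]
            trace[h, 7] = s[S_EMAX]
            trace[h, 8] = s[S_H_GAIN]
            trace[h, 9] = s[S_H_METAB]
            trace[h, 10] = s[S_H_DRAG]
            trace[h, 11] = s[S_H_TRANSFER]
            trace[h, 12] = float(ev)
            trace[h, 13] = s[S_FALIVE]
            trace[h, 14] = s[S_PALIVE]
        h += 1
    return s, trips, ntr, h
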