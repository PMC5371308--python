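"""Factorial experiment engine and derived statistics.

One *condition* is a cell of the design grid (aggregation x abundance x
distance x body length x memory type); it is simulated over ``n_maps``
landscape replicates x ``n_seals`` females per landscape.  Statistics are
aggregated per landscape first, then summarised as mean +/- SD across the
landscape replicates.  Behavioural summaries (trip distance/duration, trip
and fishing counts) use only females that completed the rearing period alive;
pup masses use surviving pups.

The optimality analysis computes the cost/benefit ratio R = E/SP per body
length (E = mean total energy spent over the rearing period, SP = pair
success), locates its minimum over length by fitting smooth curves, and
bootstraps the minimiser.  The optimal length regressed on the distance to
the resource yields the slope k2/k1 that converts a drift rate of the
foraging grounds into the matching drift of body length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .agents import LENGTH_LEVELS
from .envmap import ABUND_LEVELS, AGGREG_LEVELS, DIST_LEVELS, MapConfig, generate_field
from .params import Params
from .scheduler import SimConfig, run_simulation


@dataclass
class DesignGrid:
    aggreg: tuple = AGGREG_LEVELS
    abund: tuple = ABUND_LEVELS
    dist: tuple = DIST_LEVELS
    lengths: tuple = LENGTH_LEVELS
    mem: tuple = (0, 1)
    n_maps: int = 10
    n_seals: int = 50

    @property
    def total_runs(self) -> int:
        return (len(self.aggreg) * len(self.abund) * len(self.dist)
                * len(self.lengths) * len(self.mem) * self.n_maps * self.n_seals)

    def conditions(self) -> Iterable[tuple]:
        return itertools.product(self.aggreg, self.abund, self.dist,
                                 self.lengths, self.mem)


@dataclass
class ConditionSummary:
    aggreg: int
    abund: float
    dist: float
    length: float
    mem: int
    d_f: float
    d_p: float
    sp: float
    mean_d_trip: float
    mean_t_trip: float
    nbr_trip: float
    nbr_fishing: float
    mean_e_fish: float
    final_mass_female: float
    final_mass_pup: float
    mean_e_spent: float
    sd: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {k: v for k, v in self.__dict__.items() if k != "sd"}
        row.update({f"sd_{k}": v for k, v in self.sd.items()})
        return row


def _condition_seed(seed, aggreg, abund, dist, length, mem):
    """Deterministic, condition-distinct seed material."""
    return np.random.SeedSequence(
        [int(seed), int(aggreg), int(abund), int(dist), int(length), int(mem)]
    )


def run_condition(aggreg, abund, dist, length, mem, n_maps=10, n_seals=50,
                  seed=0, params: Optional[Params] = None,
                  collect_runs: bool = False):
    """Simulate one design cell; returns a ConditionSummary.

    With ``collect_runs=True`` also returns the per-run DataFrame (survival
    flags, masses, energy spent) used by the bootstrap.
    """
    params = params or Params()
    ss = _condition_seed(seed, aggreg, abund, dist, length, mem)
    children = ss.spawn(n_maps)
    per_map = []
    runs = []
    for m in range(n_maps):
        map_seed, *seal_seeds = children[m].generate_state(1 + n_seals)
        rmap = generate_field(
            MapConfig(aggreg=aggreg, abund=abund, dist=dist,
                      rep_map=m + 1, seed=int(map_seed) % 2**31),
            params,
        )
        rows = []
        for k in range(n_seals):
            res = run_simulation(SimConfig(
                map=rmap, length=length, mem=mem, rep=k + 1,
                seed=int(seal_seeds[k]) % 2**31, params=params))
            rows.append(dict(
                map_rep=m + 1, seal_rep=k + 1,
                f_surv=res.female_survived, p_surv=res.pup_survived,
                w_f=res.final_mass_female, w_p=res.final_mass_pup,
                n_trips=res.n_trips,
                mean_d_trip=res.mean_trip_distance,
                mean_t_trip=res.mean_trip_duration,
                n_fishing=res.n_fishing_events,
                e_won=sum(t.e_won for t in res.trips),
                e_spent=res.total_energy_spent,
            ))
        df = pd.DataFrame(rows)
        runs.append(df)
        surv = df[df.f_surv]
        per_map.append(dict(
            d_f=1.0 - df.f_surv.mean(),
            d_p=1.0 - df.p_surv.mean(),
            sp=df.f_surv.mean() * df.p_surv.mean(),
            mean_d_trip=surv.mean_d_trip.mean(),
            mean_t_trip=surv.mean_t_trip.mean(),
            nbr_trip=surv.n_trips.mean(),
            nbr_fishing=surv.n_fishing.mean(),
            mean_e_fish=(surv.e_won.sum() / surv.n_fishing.sum()
                         if surv.n_fishing.sum() > 0 else np.nan),
            final_mass_female=surv.w_f.mean(),
            final_mass_pup=df.loc[df.p_surv, "w_p"].mean(),
            mean_e_spent=df.e_spent.mean(),
        ))
    pm = pd.DataFrame(per_map)
    summary = ConditionSummary(
        aggreg=aggreg, abund=abund, dist=dist, length=length, mem=mem,
        **{k: float(pm[k].mean()) for k in pm.columns},
        sd={k: float(pm[k].std(ddof=1)) for k in pm.columns},
    )
    if collect_runs:
        return summary, pd.concat(runs, ignore_index=True)
    return summary


def run_design(grid: DesignGrid, seed=0, params: Optional[Params] = None,
               progress: bool = False) -> pd.DataFrame:
    """One ConditionSummary row per design-grid cell (order-independent)."""
    rows = []
    for cond in grid.conditions():
        s = run_condition(*cond, n_maps=grid.n_maps, n_seals=grid.n_seals,
                          seed=seed, params=params)
        rows.append(s.as_row())
        if progress:
            print(f"done {cond}", flush=True)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optimality analysis
# ---------------------------------------------------------------------------
def cost_benefit(total_energy_per_run, sp: float) -> float:
    """R = E / SP with E the mean total energy spent over the rearing period."""
    e = float(np.mean(total_energy_per_run))
    if e < 0:
        raise ValueError("energies must be non-negative")
    if sp <= 0:
        return np.inf
    if sp > 1:
        raise ValueError("SP must lie in (0, 1]")
    return e / sp


def _r_from_sample(df: pd.DataFrame) -> float:
    sp = df.f_surv.mean() * df.p_surv.mean()
    if sp <= 0:
        return np.inf
    return df.e_spent.mean() / sp


def _curve_argmin(lengths, r_values, lo=85.0, hi=145.0):
    """Minimiser over [lo, hi] of the better of a quadratic and a cubic fit."""
    grid = np.linspace(lo, hi, 601)
    best_val = np.inf
    best_arg = np.nan
    finite = np.isfinite(r_values)
    x, y = np.asarray(lengths)[finite], np.asarray(r_values)[finite]
    if len(x) < 3:
        return np.nan
    for deg in (2, 3):
        if len(x) <= deg:
            continue
        coef = np.polyfit(x, y, deg)
        vals = np.polyval(coef, grid)
        k = int(np.argmin(vals))
        if vals[k] < best_val:
            best_val = vals[k]
            best_arg = grid[k]
    return float(best_arg)


@dataclass
class OptimalityResult:
    r_by_length: dict
    optimal_length: float
    ci_low: float
    ci_high: float


def bootstrap_optimum(runs_by_length: dict, n_boot: int = 1000,
                      seed: int = 0) -> OptimalityResult:
    """Bootstrap the body length minimising R = E/SP.

    ``runs_by_length`` maps each length to its per-run DataFrame (columns
    f_surv, p_surv, e_spent).  Each bootstrap resamples runs with replacement
    within each length, refits the R(length) curves, and records the
    minimiser; the 2.5 and 97.5 percentiles bound the optimum.
    """
    lengths = sorted(runs_by_length)
    if len(lengths) < 2:
        raise ValueError("need at least two lengths")
    r_point = {L: _r_from_sample(runs_by_length[L]) for L in lengths}
    opt = _curve_argmin(lengths, [r_point[L] for L in lengths])
    rng = np.random.default_rng(seed)
    argmins = np.empty(n_boot)
    for b in range(n_boot):
        rs = []
        for L in lengths:
            df = runs_by_length[L]
            idx = rng.integers(0, len(df), len(df))
            rs.append(_r_from_sample(df.iloc[idx]))
        argmins[b] = _curve_argmin(lengths, rs)
    ok = np.isfinite(argmins)
    lo, hi = (np.percentile(argmins[ok], [2.5, 97.5]) if ok.any()
              else (np.nan, np.nan))
    return OptimalityResult(r_by_length=r_point, optimal_length=opt,
                            ci_low=float(lo), ci_high=float(hi))


def optimal_length_regression(optima_by_dist: dict,
                              front_shift_km_per_year: float | None = None):
    """Least-squares line through (Dist, optimal length).

    Returns (slope, intercept) in cm per km; the slope is the ratio k2/k1 of
    the body-length drift rate to the resource-distance drift rate.  With a
    front-shift speed the implied body-length drift (cm per year) is
    slope x speed.
    """
    d = {k: v for k, v in optima_by_dist.items() if np.isfinite(v)}
    if len(d) < 3:
        raise ValueError("need optima for at least three distances")
    x = np.array(sorted(d))
    y = np.array([d[k] for k in x])
    fit = stats.linregress(x, y)
    if front_shift_km_per_year is None:
        return fit.slope, fit.intercept
    return fit.slope, fit.intercept, fit.slope * front_shift_km_per_year
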