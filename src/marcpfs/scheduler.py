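"""Drive one simulation: phase schedule and the hourly loop.

A run covers the 15-day prenatal prospection, a 5-7-day perinatal shore fast,
and the 2880-hour rearing period in which the female alternates foraging trips
with shore visits.  The hourly loop is the compiled kernel; this module wraps
it with configuration, result containers and an optional hourly trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernel
from ._kernel import (
    MAX_HOURS,
    N_STATE,
    S_EPUP,
    S_ESEAL,
    S_ESPENT,
    S_FALIVE,
    S_NFISH,
    S_NTRIP,
    S_PALIVE,
    S_SUM_TD,
    S_SUM_TH,
)
from .agents import LENGTH_LEVELS
from .envmap import MapConfig, ResourceMap, generate_field
from .params import Params

TRACE_COLUMNS = ["t", "phase", "at_sea", "x", "y", "e_seal", "e_pup", "e_max",
                 "gain", "metabolic", "drag", "transfer", "event",
                 "female_alive", "pup_alive"]


@dataclass
class SimConfig:
    """One simulation: a landscape, a female phenotype, and a seed."""

    map: "ResourceMap | MapConfig"
    length: float = 115.0
    mem: int = 1
    rep: int = 1
    seed: int = 0
    params: Params = field(default_factory=Params)

    def __post_init__(self):
        if self.length not in LENGTH_LEVELS:
            raise ValueError(f"length must be one of {LENGTH_LEVELS}")
        if self.mem not in (0, 1):
            raise ValueError("mem must be 0 or 1")


@dataclass
class TripLog:
    t_start: float
    t_end: float
    distance: float
    n_fishing_events: int
    e_won: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SimulationResult:
    female_survived: bool
    pup_survived: bool
    final_mass_female: float
    final_mass_pup: float
    trips: list
    total_energy_spent: float
    n_fishing_events: int
    fishing_map: np.ndarray
    trace: Optional[pd.DataFrame] = None

    @property
    def n_trips(self) -> int:
        return len(self.trips)

    @property
    def mean_trip_distance(self) -> float:
        return float(np.mean([t.distance for t in self.trips])) if self.trips else np.nan

    @property
    def mean_trip_duration(self) -> float:
        return float(np.mean([t.duration for t in self.trips])) if self.trips else np.nan


def _resolve_map(m) -> ResourceMap:
    return generate_field(m) if isinstance(m, MapConfig) else m


def run_simulation(config: SimConfig, trace: bool = False) -> SimulationResult:
    """Execute one full run; deterministic given (config, seed)."""
    rmap = _resolve_map(config.map)
    p = config.params.to_array(config.length, config.mem)
    ix, iy = rmap.island_xy_km
    fishmap = np.zeros((100, 100), dtype=np.float64)
    tr = np.zeros((MAX_HOURS if trace else 1, _kernel.TRACE_COLS))
    seed = int(config.seed) % (2**32 - 1)
    s, trips_arr, ntr, hours = _kernel.run_core(
        np.ascontiguousarray(rmap.values, dtype=np.float64),
        rmap.avg_env, ix, iy, p, seed, fishmap, tr, trace,
    )
    trips = [TripLog(t[0], t[1], t[2], int(t[3]), t[4]) for t in trips_arr[:ntr]]
    trace_df = None
    if trace:
        trace_df = pd.DataFrame(tr[:hours], columns=TRACE_COLUMNS)
    return SimulationResult(
        female_survived=s[S_FALIVE] > 0.5,
        pup_survived=s[S_PALIVE] > 0.5,
        final_mass_female=s[S_ESEAL] / config.params.econtent_seal,
        final_mass_pup=s[S_EPUP] / config.params.econtent_pup,
        trips=trips,
        total_energy_spent=s[S_ESPENT],
        n_fishing_events=int(s[S_NFISH]),
        fishing_map=fishmap,
        trace=trace_df,
    )


def simulate_hour(state: np.ndarray, rmap: ResourceMap, params_vector: np.ndarray,
                  fishmap: Optional[np.ndarray] = None) -> int:
    """Advance a raw kernel state vector by one hour; returns the event mask.

    Low-level hook for step-by-step inspection and invariant tests.  The
    state layout is documented in :mod:`._kernel`; create a fresh state with
    :func:`new_state`.  Kernel randomness is numba's global stream: seed it
    with ``seed_kernel_rng`` for reproducible stepping.
    """
    if fishmap is None:
        fishmap = np.zeros((100, 100), dtype=np.float64)
    ix, iy = rmap.island_xy_km
    return int(_kernel._step(state, np.ascontiguousarray(rmap.values, float),
                             rmap.avg_env, ix, iy, params_vector, fishmap))


def new_state(params_vector: np.ndarray, rmap: ResourceMap) -> np.ndarray:
    """Fresh kernel state at the start of the prenatal phase."""
    ix, iy = rmap.island_xy_km
    return _kernel.init_state(params_vector, ix, iy)


def seed_kernel_rng(seed: int) -> None:
    """Seed the compiled kernel's random stream (for stepwise use)."""
    _kernel._seed_rng(int(seed) % (2**32 - 1))
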