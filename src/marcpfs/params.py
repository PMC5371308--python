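"""Model constants and the flat parameter vector consumed by the simulation kernel.

Every biological constant of the model lives in :class:`Params` so that any value
can be overridden for sensitivity runs.  The dataclass mirrors the published
parameter table of the fur-seal rearing model (energy contents, field metabolic
rate, swimming speed, satiation, lethal fractions, phase durations); fields whose
values the source literature leaves open (milk-transfer rate, shore metabolic
factor, return-probability shape, memory fidelity, landscape-scale mapping) carry
the calibrated defaults documented in ``docs/methods.md``.

Units: energy MJ, mass kg, length cm, distance km, time h unless noted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

# ---------------------------------------------------------------------------
# derived physical conversions
# ---------------------------------------------------------------------------

#: MJ kg^-1 h^-1 per W kg^-1 (1 W kg^-1 = 3600 J kg^-1 h^-1)
W_KG_TO_MJ_KG_H = 3600.0e-6

#: grams of catchable prey per map abundance unit (1.5 units <-> 55 g h^-1)
GRAMS_PER_UNIT = 55.0 / 1.5

#: kJ per kcal
KJ_PER_KCAL = 4.184


@dataclass
class Params:
    """Tunable model parameters with field defaults.

    Attributes follow the model's vocabulary: ``econtent_*`` are tissue energy
    densities (MJ kg^-1), ``fmr_sea`` the at-sea field metabolic rate (W kg^-1),
    ``v`` the swimming speed (m s^-1).  See docs/methods.md for the calibrated
    (starred) parameters.
    """

    # --- energetics (published) ---
    econtent_seal: float = 10.59      # MJ kg^-1
    econtent_pup: float = 8.24        # MJ kg^-1
    fmr_sea: float = 6.09             # W kg^-1, at-sea metabolic rate
    v: float = 2.11                   # m s^-1 swimming speed
    satiation_frac: float = 0.07      # per-feeding intake cap, fraction of E at dawn
    emax_factor: float = 1.07         # E_max = 1.07 x mass(end of former night)
    pup_loss_per_hour: float = 0.0012  # fasting pup energy loss per hour
    kcal_per_g: float = 4.0           # fish mass (g) -> kcal
    w_initpup: float = 5.5            # kg at birth
    w_maxpup: float = 18.0            # kg cap
    perinatal_gain_kg: float = 1.5    # pup mass gain over the perinatal fast
    min_fish_units: float = 1.5       # profitability threshold (~55 g h^-1)
    drag_85: float = 0.041            # MJ km^-1 displacement cost, 85 cm female
    drag_145: float = 0.12            # MJ km^-1, 145 cm female (anchor, see docs)

    # --- mortality (published) ---
    lethal_frac_female: float = 0.70  # death centred at 70% of E_init
    lethal_frac_pup: float = 0.56     # death centred at 56% of post-suckling energy
    mort_sd_pct: float = 2.0          # probit width, percentage points (*)

    # --- schedule (published) ---
    t_rearing_h: int = 2880           # 120 d rearing
    prenatal_h: int = 360             # 15 d prospection
    perinatal_days_min: int = 5
    perinatal_days_max: int = 7
    departure_hour: int = 17          # preferred shore-departure hour
    night_start: int = 22             # night = [22, 06), 8 h
    night_end: int = 6
    mta_h: float = 48.0               # mean time ashore, 2 d
    t_max_trip_h: float = 216.0       # trip-length ceiling, 9 d (*)
    d_max_km: float = 500.0           # foraging range limit

    # --- calibrated behavioural/energetic parameters (*) ---
    shore_metab_factor: float = 0.25  # ashore metabolic rate as fraction of FMR_sea
    r_milk: float = 0.0035            # per shore-hour transfer = r x donation surplus
    milk_floor_frac: float = 0.85     # fraction of E_init a mother will not give away
    milk_eff: float = 1.0             # pup energy gained per MJ withdrawn
    g_half: float = 0.05              # MJ h^-1 half-saturation of memory fidelity
    mem_lambda_km: float = 250.0      # e-folding of the distance discount applied
                                      # when memorising rich cells (closer preferred)
    nav_error_frac: float = 0.1      # sd of the landing scatter when travelling
                                      # to a memorised cell, as a fraction of the
                                      # transit distance
    orbit_frac: float = 0.6           # head back to the best cell when the local
                                      # abundance falls below this fraction of it
    ret_k: float = 40.0               # return-probability logistic steepness
    ret_x0: float = 0.25              # logistic midpoint on (E - E_wb)/E_max
    ret_ramp_coeff: float = 0.5       # trip-clock ramp amplitude
    ret_ramp_pow: float = 4.0         # trip-clock ramp exponent
    satiety_margin: float = 0.5       # MJ of headroom below E_max required to fish
    full_frac: float = 0.97           # dawn energy fraction of E_max that ends
                                      # the trip (load complete)
    min_trip_h: float = 60.0          # no load-complete return before this
    crw_sigma: float = 1.5475         # rad, turning-angle sd (lag-1 autocorr 0.30)
    crw_sigma_search: float = 0.30    # rad, turning sd while crossing barren cells
    start_hour: int = 17              # hour of day at simulation start (departure)
    min_shore_h: float = 48.0         # earliest departure after arrival
    max_shore_h: float = 72.0         # visits last 1-3 d

    # --- geometry ---
    cell_km: float = 10.0
    n_cells: int = 100
    plateau_km: float = 50.0

    # ------------------------------------------------------------------
    @property
    def v_kmh(self) -> float:
        """Swimming speed in km h^-1 (2.11 m s^-1 -> 7.596 km h^-1)."""
        return self.v * 3.6

    @property
    def fmr_mj_kg_h(self) -> float:
        """Mass-specific metabolic rate in MJ kg^-1 h^-1."""
        return self.fmr_sea * W_KG_TO_MJ_KG_H

    @property
    def drag_coeff(self) -> float:
        """Quadratic drag coefficient a with drag(L) = a L^2 (MJ km^-1 cm^-2).

        A streamlined body has cross-section S proportional to L^2, and the
        published endpoint costs (0.041 MJ km^-1 at 85 cm, 0.12 at 145 cm) are
        in ratio 2.93 ~= (145/85)^2, so a single quadratic through the lower
        anchor reproduces both printed values.
        """
        return self.drag_85 / 85.0**2

    def replace(self, **kw) -> "Params":
        return dataclasses.replace(self, **kw)

    # ------------------------------------------------------------------
    def to_array(self, length: float, mem: int) -> np.ndarray:
        """Pack parameters plus the per-run (length, mem) into the kernel vector."""
        a = np.empty(N_PARAMS, dtype=np.float64)
        a[P_ECONT_SEAL] = self.econtent_seal
        a[P_ECONT_PUP] = self.econtent_pup
        a[P_FMR] = self.fmr_mj_kg_h
        a[P_SHORE_FACTOR] = self.shore_metab_factor
        a[P_V_KMH] = self.v_kmh
        a[P_DRAG_COEFF] = self.drag_coeff
        a[P_LENGTH] = length
        a[P_GRAMS_PER_UNIT] = GRAMS_PER_UNIT
        a[P_KCAL_PER_G] = self.kcal_per_g
        a[P_KJ_PER_KCAL] = KJ_PER_KCAL
        a[P_SAT_FRAC] = self.satiation_frac
        a[P_EMAX_FACTOR] = self.emax_factor
        a[P_PUP_LOSS] = self.pup_loss_per_hour
        a[P_W_INITPUP] = self.w_initpup
        a[P_W_MAXPUP] = self.w_maxpup
        a[P_PERI_GAIN] = self.perinatal_gain_kg
        a[P_MIN_FISH_U] = self.min_fish_units
        a[P_LETHAL_F] = self.lethal_frac_female
        a[P_LETHAL_P] = self.lethal_frac_pup
        a[P_MORT_SD] = self.mort_sd_pct
        a[P_T_REAR] = float(self.t_rearing_h)
        a[P_PRENATAL_H] = float(self.prenatal_h)
        a[P_PERI_MIN_D] = float(self.perinatal_days_min)
        a[P_PERI_MAX_D] = float(self.perinatal_days_max)
        a[P_DEP_HOUR] = float(self.departure_hour)
        a[P_NIGHT_START] = float(self.night_start)
        a[P_NIGHT_END] = float(self.night_end)
        a[P_MIN_SHORE] = self.min_shore_h
        a[P_MAX_SHORE] = self.max_shore_h
        a[P_T_MAX_TRIP] = self.t_max_trip_h
        a[P_R_MILK] = self.r_milk
        a[P_MILK_FLOOR] = self.milk_floor_frac
        a[P_MILK_EFF] = self.milk_eff
        a[P_G_HALF] = self.g_half
        a[P_ORBIT_FRAC] = self.orbit_frac
        a[P_MEM_LAMBDA] = self.mem_lambda_km
        a[P_NAV_ERR] = self.nav_error_frac
        a[P_RET_K] = self.ret_k
        a[P_RET_X0] = self.ret_x0
        a[P_RET_RAMP_C] = self.ret_ramp_coeff
        a[P_RET_RAMP_P] = self.ret_ramp_pow
        a[P_FULL_FRAC] = self.full_frac
        a[P_SAT_MARGIN] = self.satiety_margin
        a[P_MIN_TRIP_H] = self.min_trip_h
        a[P_CRW_SIGMA] = self.crw_sigma
        a[P_CRW_SIGMA_SEARCH] = self.crw_sigma_search
        a[P_START_HOUR] = float(self.start_hour)
        a[P_CELL_KM] = self.cell_km
        a[P_MEM] = float(mem)
        a[P_D_MAX] = self.d_max_km
        return a


# ---------------------------------------------------------------------------
# kernel parameter-vector indices
# ---------------------------------------------------------------------------
(
    P_ECONT_SEAL,
    P_ECONT_PUP,
    P_FMR,
    P_SHORE_FACTOR,
    P_V_KMH,
    P_DRAG_COEFF,
    P_LENGTH,
    P_GRAMS_PER_UNIT,
    P_KCAL_PER_G,
    P_KJ_PER_KCAL,
    P_SAT_FRAC,
    P_EMAX_FACTOR,
    P_PUP_LOSS,
    P_W_INITPUP,
    P_W_MAXPUP,
    P_PERI_GAIN,
    P_MIN_FISH_U,
    P_LETHAL_F,
    P_LETHAL_P,
    P_MORT_SD,
    P_T_REAR,
    P_PRENATAL_H,
    P_PERI_MIN_D,
    P_PERI_MAX_D,
    P_DEP_HOUR,
    P_NIGHT_START,
    P_NIGHT_END,
    P_MIN_SHORE,
    P_MAX_SHORE,
    P_T_MAX_TRIP,
    P_R_MILK,
    P_MILK_FLOOR,
    P_MILK_EFF,
    P_G_HALF,
    P_ORBIT_FRAC,
    P_MEM_LAMBDA,
    P_NAV_ERR,
    P_RET_K,
    P_RET_X0,
    P_RET_RAMP_C,
    P_RET_RAMP_P,
    P_FULL_FRAC,
    P_SAT_MARGIN,
    P_MIN_TRIP_H,
    P_CRW_SIGMA,
    P_CRW_SIGMA_SEARCH,
    P_START_HOUR,
    P_CELL_KM,
    P_MEM,
    P_D_MAX,
) = range(50)
N_PARAMS = 50

DEFAULT_PARAMS = Params()
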