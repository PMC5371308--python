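"""Hourly energy bookkeeping: metabolism, fishing gains, starvation, milk.

Conventions: the at-sea metabolic rate is 6.09 W kg^-1 (0.021924 MJ kg^-1
h^-1); fish mass converts at 4 kcal g^-1 and 4.184 kJ kcal^-1, so the
profitability threshold of 55 g h^-1 is worth 0.9205 MJ per fishing hour.
Satiation caps each feeding at 7% of the female's energy at the end of the
former night, and her energy can never exceed the fixed ceiling E_max = 1.07 x
her initial mass expressed in energy terms — the latter is the constraint that
actually limits nightly growth.
"""

from __future__ import annotations

from . import _kernel
from .agents import FemaleState, PupState
from .params import GRAMS_PER_UNIT, KJ_PER_KCAL, Params

_DEFAULT = Params()


def metabolic_cost_hour(w_seal: float, params: Params = _DEFAULT) -> float:
    """At-sea metabolic expenditure for one hour (MJ)."""
    if w_seal <= 0:
        raise ValueError("mass must be positive")
    return params.fmr_mj_kg_h * w_seal


def fishing_gain(abundance: float, e_seal: float, e_max: float,
                 night_start_energy: float, params: Params = _DEFAULT,
                 units: str = "g/h") -> float:
    """Energy won in one fishing hour (MJ), after satiation and E_max caps.

    ``abundance`` is the local prey abundance, in g h^-1 by default or in map
    units (1 unit = 36.67 g h^-1) with ``units='units'``.
    """
    if abundance < 0:
        raise ValueError("abundance must be non-negative")
    ab_gh = abundance * GRAMS_PER_UNIT if units == "units" else abundance
    return float(_kernel.fishing_gain(
        ab_gh, e_seal, e_max, night_start_energy,
        params.satiation_frac, params.kcal_per_g, KJ_PER_KCAL,
    ))


def update_emax(w_end_of_night: float, params: Params = _DEFAULT) -> float:
    """Dawn update of the energy ceiling: 1.07 x mass at end of former night."""
    return params.emax_factor * w_end_of_night * params.econtent_seal


def pup_starve_hour(pup: PupState, params: Params = _DEFAULT) -> PupState:
    """One hour of fasting: the pup loses 0.12% of its energy."""
    pup.e_pup *= 1.0 - params.pup_loss_per_hour
    return pup


def suckle_hour(female: FemaleState, pup: PupState,
                rate_param: float | None = None,
                params: Params = _DEFAULT) -> tuple:
    """One shore hour of suckling.

    The transfer is r x the mother's donation surplus — the energy she holds
    above the fraction of her initial stores she will not give away (a
    depleted mother protects her own reserve first).  It is truncated so the
    pup never exceeds its 18 kg mass cap and the female never goes below zero
    energy.  The pup's post-suckling reference is the caller's responsibility
    (it is set once per bout, at departure).
    """
    r = params.r_milk if rate_param is None else rate_param
    surplus = female.e_seal - params.milk_floor_frac * female.e_init
    tr = max(r * surplus, 0.0)
    room = max(pup.w_max * pup.econtent - pup.e_pup, 0.0) / params.milk_eff
    tr = min(tr, room, female.e_seal)
    female.e_seal -= tr
    pup.e_pup += tr * params.milk_eff
    female.t_suckling += 1
    return female, pup
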