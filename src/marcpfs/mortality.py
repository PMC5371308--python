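"""Starvation mortality and the pair-success statistic.

Death is a per-hour Bernoulli draw whose probability is a Normal CDF of the
animal's current energy as a percentage of its reference: centred at 70% for
females (reference = initial energy) and 56% for pups (reference = energy
after the last suckling bout).  The distribution width is two percentage
points: smooth, but sharp enough that the rule acts as a near-threshold under
hourly draws.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _kernel


@dataclass
class MortalityModel:
    mean_frac_female: float = 70.0   # % of reference energy
    mean_frac_pup: float = 56.0
    spread: float = 2.0              # sd, percentage points

    def __post_init__(self):
        if not 0 < self.mean_frac_pup < self.mean_frac_female < 100:
            raise ValueError("need 0 < pup threshold < female threshold < 100")


def p_death(current_energy: float, reference_energy: float,
            model: MortalityModel | None = None, who: str = "female") -> float:
    """Hourly death probability; exactly 0.5 at the lethal percentage."""
    model = model or MortalityModel()
    if reference_energy <= 0:
        raise ValueError("reference energy must be positive")
    frac = (model.mean_frac_female if who == "female"
            else model.mean_frac_pup) / 100.0
    return float(_kernel.p_death_probit(current_energy, reference_energy,
                                        frac, model.spread))


def pair_success(d_f: float, d_p: float) -> float:
    """SP = (1 - D_f)(1 - D_p), the breeding-success statistic."""
    if not (0.0 <= d_f <= 1.0 and 0.0 <= d_p <= 1.0):
        raise ValueError("mortality probabilities must lie in [0, 1]")
    return (1.0 - d_f) * (1.0 - d_p)
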