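"""Metabolizable-energy requirements and intake back-calculation.

During the grazing phase, individual intake cannot be measured directly, so
daily DMI is estimated by summing the cow's ME requirements — maintenance,
walking activity, body-weight change and milk synthesis — and dividing by
the ME concentration of the pasture consumed.

Unit note: the milk-energy coefficients (0.0929 x fat % + 0.0547 x CP % +
0.0395 x lactose %) give gross energy in Mcal per kg of milk. The quotient
by the lactation efficiency (0.65) is still in Mcal/d; dividing by
0.238 Mcal/MJ converts to MJ/d, the unit of the other three terms. A config
flag (`literal_mcal_conversion`) multiplies instead, reproducing the source
arithmetic verbatim for audit purposes only.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .config import EnergyConfig
from .errors import DegenerateInputError, InvalidArgumentError
from .types import EnergyRequirement, MilkRecord

_DEFAULT = EnergyConfig()


def maintenance_mj(bw: float, config: EnergyConfig = _DEFAULT) -> float:
    """Maintenance requirement, 0.56 MJ per kg of metabolic weight (BW^0.75)."""
    if bw <= 0:
        raise InvalidArgumentError(f"bw must be > 0, got {bw}")
    return config.maintenance_mj_per_kg075 * bw**0.75


def activity_mj(bw: float, km_walked: float, config: EnergyConfig = _DEFAULT) -> float:
    """Walking cost, 0.0037 MJ per kg BW per horizontal kilometre."""
    if bw <= 0:
        raise InvalidArgumentError(f"bw must be > 0, got {bw}")
    if km_walked < 0:
        raise InvalidArgumentError(f"km_walked must be >= 0, got {km_walked}")
    return config.activity_mj_per_kg_km * bw * km_walked


def estimate_daily_bw_change(bw_series: Sequence[tuple[float, float]]) -> float:
    """Average daily BW change: the OLS slope of BW (kg) on day.

    ``bw_series`` is an ordered sequence of (day, kg) pairs covering at
    least two distinct days.
    """
    if len(bw_series) < 2:
        raise InvalidArgumentError("need at least 2 (day, bw) observations")
    days = np.asarray([d for d, _ in bw_series], dtype=float)
    bws = np.asarray([w for _, w in bw_series], dtype=float)
    if np.ptp(days) == 0:
        raise DegenerateInputError("all days identical; slope undefined")
    slope = np.polyfit(days, bws, 1)[0]
    return float(slope)


def bw_change_mj(
    delta_bw: float, energy_per_kg: float | None = None, config: EnergyConfig = _DEFAULT
) -> float:
    """Energy cost (gain) or supply (loss) of body-weight change, MJ/d.

    Negative ``delta_bw`` returns negative energy: tissue mobilised spares
    dietary ME. The coefficient defaults to ``config.bw_change_mj_per_kg``.
    """
    coef = config.bw_change_mj_per_kg if energy_per_kg is None else energy_per_kg
    if coef <= 0:
        raise InvalidArgumentError(f"energy_per_kg must be > 0, got {coef}")
    return delta_bw * coef


def milk_energy_mj(milk: MilkRecord, config: EnergyConfig = _DEFAULT) -> float:
    """ME required for the day's milk, MJ/d.

    Per-kg gross energy (Mcal/kg) from fat, CP and lactose percentages,
    times yield, over the lactation efficiency, converted Mcal -> MJ.
    """
    per_kg_mcal = (
        config.milk_fat_coef * milk.fat_pct
        + config.milk_cp_coef * milk.cp_pct
        + config.milk_lactose_coef * milk.lactose_pct
    )
    total_mcal = per_kg_mcal * milk.yield_kg / config.lactation_efficiency
    if config.literal_mcal_conversion:
        return total_mcal * config.mcal_per_mj
    return total_mcal / config.mcal_per_mj


def requirement(
    bw: float,
    km_walked: float,
    delta_bw: float,
    milk: MilkRecord,
    config: EnergyConfig = _DEFAULT,
) -> EnergyRequirement:
    """Assemble the four-term additive ME requirement for one cow-day."""
    return EnergyRequirement(
        maintenance_mj=maintenance_mj(bw, config),
        activity_mj=activity_mj(bw, km_walked, config),
        bw_change_mj=bw_change_mj(delta_bw, config=config),
        milk_mj=milk_energy_mj(milk, config),
    )


def back_calculate_dmi(req: EnergyRequirement, diet_me: float) -> float:
    """DMI (kg DM/d) implied by a total ME requirement at a given diet ME
    concentration (MJ/kg DM)."""
    if diet_me <= 0:
        raise InvalidArgumentError(f"diet_me must be > 0, got {diet_me}")
    return req.total_mj / diet_me
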