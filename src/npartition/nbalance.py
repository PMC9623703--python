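"""Four-way nitrogen balance: intake, fecal, milk and urinary N.

Urinary N is estimated by difference — total N intake minus fecal and milk
N — under the assumption that N retention is negligible in non-pregnant
mid-lactation cows with stable body condition. The closure identity
``intake = fecal + milk + urine`` therefore holds exactly on every row.
Negative urine estimates are flagged, never clipped, so that generator or
data faults remain visible downstream.

Conversions used throughout: crude protein = N x 6.25 (feed), and
milk N % = milk CP % / 6.38 (milk protein has a higher N content than the
generic feed-protein factor assumes).
"""
from __future__ import annotations

import warnings
from enum import Enum
from typing import Iterable, Optional, Sequence

from .config import BalanceConfig
from .errors import ImplausibleValueWarning, InvalidArgumentError
from .types import NBalanceResult, StallDayRecord

_DEFAULT = BalanceConfig()

#: Feed-protein nitrogen factor: CP (g) per g N.
CP_PER_N = 6.25
#: Milk-protein nitrogen factor: milk CP (g) per g N.
MILK_CP_PER_N = 6.38


class FecalBasis(str, Enum):
    WET = "wet"
    DRY = "dry"


def n_intake(
    dmi_kg: float, pasture_cp_pct: float, urea_g: float, urea_n_fraction: float = 0.466
) -> float:
    """Total N intake (g/d) from pasture plus urea.

    Pasture N is DMI x CP% / 6.25; urea contributes its N fraction directly
    (feed-grade urea is about 46.6% N).
    """
    if min(dmi_kg, pasture_cp_pct, urea_g) < 0:
        raise InvalidArgumentError("intake components must be >= 0")
    if not 0 < urea_n_fraction < 1:
        raise InvalidArgumentError("urea_n_fraction must be in (0, 1)")
    return dmi_kg * 1000.0 * (pasture_cp_pct / 100.0) / CP_PER_N + urea_g * urea_n_fraction


def diet_cp_pct(n_intake_g: float, dmi_kg: float) -> float:
    """CP concentration of the whole diet (% of DM) implied by N intake."""
    if dmi_kg <= 0:
        raise InvalidArgumentError(f"dmi_kg must be > 0, got {dmi_kg}")
    return n_intake_g * CP_PER_N / (dmi_kg * 1000.0) * 100.0


def milk_n(yield_kg: float, milk_cp_pct: float) -> float:
    """Milk N output (g/d): yield x (CP% / 6.38)."""
    if yield_kg < 0 or milk_cp_pct < 0:
        raise InvalidArgumentError("milk inputs must be >= 0")
    return yield_kg * 1000.0 * (milk_cp_pct / 100.0) / MILK_CP_PER_N


def milk_n_pct(milk_cp_pct: float) -> float:
    """Milk N as a percentage of milk: CP % / 6.38."""
    return milk_cp_pct / MILK_CP_PER_N


def fecal_n(
    mass_kg: float,
    n_conc_g_per_kg: float,
    conc_basis: FecalBasis | str = FecalBasis.WET,
    mass_basis: FecalBasis | str = FecalBasis.WET,
    dm_pct: Optional[float] = None,
) -> float:
    """Total fecal N (g/d): fecal mass, on the concentration's basis, times
    the N concentration.

    When the mass and the concentration are on different bases (wet vs dry),
    ``dm_pct`` (fecal DM %) is required to convert the mass.
    """
    conc_basis = FecalBasis(conc_basis)
    mass_basis = FecalBasis(mass_basis)
    if mass_kg < 0 or n_conc_g_per_kg < 0:
        raise InvalidArgumentError("fecal mass and concentration must be >= 0")
    if mass_basis != conc_basis:
        if dm_pct is None:
            raise InvalidArgumentError(
                f"mass on {mass_basis.value} basis but concentration on "
                f"{conc_basis.value} basis: dm_pct is required"
            )
        if not 0 < dm_pct <= 100:
            raise InvalidArgumentError("dm_pct must be in (0, 100]")
        if mass_basis is FecalBasis.WET:  # wet -> dry
            mass_kg = mass_kg * dm_pct / 100.0
        else:  # dry -> wet
            mass_kg = mass_kg / (dm_pct / 100.0)
    return mass_kg * n_conc_g_per_kg


def urine_n_by_difference(
    n_intake_g: float, fecal_n_g: float, milk_n_g: float, n_retention_g: float = 0.0
) -> float:
    """Urinary N (g/d) as intake minus fecal, milk and (assumed zero)
    retained N. A negative result is returned as-is with an
    :class:`ImplausibleValueWarning`, never silently clipped."""
    if min(n_intake_g, fecal_n_g, milk_n_g) < 0:
        raise InvalidArgumentError("balance components must be >= 0")
    est = n_intake_g - (fecal_n_g + milk_n_g) - n_retention_g
    if est < -1e-9:  # tolerance keeps float round-off from flagging
        warnings.warn(
            f"estimated urine N is negative ({est:.1f} g/d): "
            "fecal + milk N exceed intake",
            ImplausibleValueWarning,
            stacklevel=2,
        )
    return est


def balance_row(record: StallDayRecord, config: BalanceConfig = _DEFAULT) -> NBalanceResult:
    """Nitrogen partition for a single stall cow-day."""
    dmi = record.offered_kg_dm - record.refused_kg_dm
    intake = n_intake(dmi, record.pasture.cp_pct, record.urea_g, config.urea_n_fraction)
    fec = fecal_n(
        record.fecal_wet_kg,
        record.fecal_n_g_per_kg,
        conc_basis=config.fecal_basis,
        mass_basis=FecalBasis.WET,
        dm_pct=record.fecal_dm_pct,
    )
    mlk = milk_n(record.milk.yield_kg, record.milk.cp_pct)
    urine = urine_n_by_difference(intake, fec, mlk, config.n_retention_g)
    return NBalanceResult(
        cow_id=record.cow_id,
        day=record.day,
        dmi_kg=dmi,
        n_intake_g=intake,
        fecal_n_g=fec,
        milk_n_g=mlk,
        urine_n_est_g=urine,
        diet_cp_pct=diet_cp_pct(intake, dmi) if dmi > 0 else 0.0,
        urine_n_conc_g_per_l=(
            urine / record.urine_volume_l if record.urine_volume_l else None
        ),
        flagged=urine < -1e-9,
    )


def balance_table(
    records: Iterable[StallDayRecord], config: BalanceConfig = _DEFAULT
) -> list[NBalanceResult]:
    """Apply the full N partition to a collection of stall cow-days,
    one result per record. Invalid records raise with the cow/day named
    (the record types validate on construction)."""
    with warnings.catch_warnings():
        # one summary warning per table is enough; row flags carry the detail
        warnings.simplefilter("once", ImplausibleValueWarning)
        return [balance_row(r, config) for r in records]
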