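"""Domain record types for the two experimental phases.

The study design these types mirror: a grazing phase in which mid-lactation
cows are acclimated to graded daily urea doses on top of a fixed pasture
allowance, and a metabolism-stall phase in which feed offered/refused, feces
and milk are measured per cow-day so that nitrogen intake can be partitioned
into fecal, milk and (by difference) urinary nitrogen.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .errors import InvalidArgumentError


class Treatment(str, Enum):
    """Urea supplementation level. Phase 1 uses all three; phase 2 only
    LOW_N (0 g/d) and MEDIUM_N (reduced to 250 g/d)."""

    LOW_N = "low_n"
    MEDIUM_N = "medium_n"
    HIGH_N = "high_n"


@dataclass(frozen=True)
class CowProfile:
    """Static traits and latent effects of one animal.

    ``cow_intercept_milk`` and ``cow_intercept_urinen`` are the cow-level
    random deviations (mean zero across the herd) added to milk yield (kg/d)
    and urine N (g/d) by the generator.
    """

    cow_id: str
    parity: int
    dim: int
    bw: float
    bcs: float
    treatment: Treatment
    cow_intercept_milk: float = 0.0
    cow_intercept_urinen: float = 0.0

    def __post_init__(self) -> None:
        if self.bw <= 0:
            raise InvalidArgumentError(f"bw must be > 0, got {self.bw}")
        if self.dim <= 0:
            raise InvalidArgumentError(f"dim must be > 0, got {self.dim}")
        if not (1 < self.bcs < 10):
            raise InvalidArgumentError(f"bcs must be in (1, 10), got {self.bcs}")
        if self.parity < 2:
            raise InvalidArgumentError("cows are multiparous: parity >= 2")


@dataclass(frozen=True)
class UreaScheduleEntry:
    """One constant-dose step of the acclimation ramp.

    Doses of at least 351 g/d are split into three feedings per day,
    smaller non-zero doses into two.
    """

    start_day: int
    n_days: int
    grams_per_dose: float
    doses_per_day: int

    @property
    def total_g_per_day(self) -> float:
        return self.grams_per_dose * self.doses_per_day

    @property
    def end_day(self) -> int:
        """Last day (inclusive) this entry applies to."""
        return self.start_day + self.n_days - 1

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.start_day < 1:
            raise InvalidArgumentError("schedule entry needs start_day, n_days >= 1")
        if self.grams_per_dose < 0:
            raise InvalidArgumentError("grams_per_dose must be >= 0")
        total = self.grams_per_dose * self.doses_per_day
        expected = 3 if total >= 351 else 2
        if total > 0 and self.doses_per_day != expected:
            raise InvalidArgumentError(
                f"{total:g} g/d must be given in {expected} doses, "
                f"got {self.doses_per_day}"
            )


@dataclass(frozen=True)
class PastureComposition:
    """Nutritive composition of the pasture on offer (% of DM; ME in MJ/kg DM)."""

    cp_pct: float
    ndf_pct: float
    adf_pct: float
    nsc_pct: float
    dmd_pct: float
    me: float

    def __post_init__(self) -> None:
        for name in ("cp_pct", "ndf_pct", "adf_pct", "nsc_pct", "dmd_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise InvalidArgumentError(f"{name} must be in [0, 100], got {v}")
        if self.me <= 0:
            raise InvalidArgumentError(f"me must be > 0, got {self.me}")


@dataclass(frozen=True)
class MilkRecord:
    """One day's milk yield and composition for one cow."""

    yield_kg: float
    fat_pct: float
    cp_pct: float
    lactose_pct: float

    def __post_init__(self) -> None:
        if self.yield_kg < 0:
            raise InvalidArgumentError(f"yield_kg must be >= 0, got {self.yield_kg}")
        for name in ("fat_pct", "cp_pct", "lactose_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 15:
                raise InvalidArgumentError(f"{name} must be in [0, 15], got {v}")


@dataclass(frozen=True)
class CowDayRecord:
    """One cow-day of the grazing phase."""

    cow_id: str
    day: int
    treatment: Treatment
    urea_g: float
    milk: MilkRecord
    bw: float
    km_walked: float
    pasture: PastureComposition

    def __post_init__(self) -> None:
        if self.urea_g < 0:
            raise InvalidArgumentError("urea_g must be >= 0")
        if self.km_walked < 0:
            raise InvalidArgumentError("km_walked must be >= 0")
        if self.bw <= 0:
            raise InvalidArgumentError("bw must be > 0")


@dataclass(frozen=True)
class StallDayRecord:
    """One cow-day of the metabolism-stall (total collection) phase.

    ``fecal_n_g_per_kg`` is on a wet-feces basis by default, matching the
    reported magnitudes (about 3 g N/kg of wet feces); ``fecal_dm_pct``
    allows conversion to a dry basis. ``urine_volume_l`` is informational —
    urinary N is estimated by difference, not from volume.
    """

    cow_id: str
    day: int
    treatment: Treatment
    offered_kg_dm: float
    refused_kg_dm: float
    urea_g: float
    milk: MilkRecord
    fecal_wet_kg: float
    fecal_dm_pct: float
    fecal_n_g_per_kg: float
    pasture: PastureComposition
    urine_volume_l: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.refused_kg_dm <= self.offered_kg_dm:
            raise InvalidArgumentError(
                f"cow {self.cow_id} day {self.day}: need "
                f"0 <= refused ({self.refused_kg_dm}) <= offered ({self.offered_kg_dm})"
            )
        for name in ("urea_g", "fecal_wet_kg", "fecal_n_g_per_kg"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(
                    f"cow {self.cow_id} day {self.day}: {name} must be >= 0"
                )
        if not 0 <= self.fecal_dm_pct <= 100:
            raise InvalidArgumentError("fecal_dm_pct must be in [0, 100]")
        if self.urine_volume_l is not None and self.urine_volume_l <= 0:
            raise InvalidArgumentError("urine_volume_l must be > 0 when present")


@dataclass(frozen=True)
class NBalanceResult:
    """Four-way nitrogen partition for one cow-day.

    The closure identity ``n_intake_g = fecal_n_g + milk_n_g + urine_n_est_g``
    holds exactly because urinary N is defined by difference (N retention
    assumed zero). A negative urine estimate is retained and ``flagged``
    rather than clipped, so data faults stay visible.
    """

    cow_id: str
    day: int
    dmi_kg: float
    n_intake_g: float
    fecal_n_g: float
    milk_n_g: float
    urine_n_est_g: float
    diet_cp_pct: float
    urine_n_conc_g_per_l: Optional[float] = None
    flagged: bool = False


@dataclass(frozen=True)
class EnergyRequirement:
    """Additive metabolizable-energy requirement of one cow-day (MJ/d)."""

    maintenance_mj: float
    activity_mj: float
    bw_change_mj: float
    milk_mj: float

    @property
    def total_mj(self) -> float:
        return self.maintenance_mj + self.activity_mj + self.bw_change_mj + self.milk_mj


@dataclass(frozen=True)
class SplitLineFit:
    """Continuous two-segment linear fit with estimated breakpoint.

    Predicted response: ``intercept + slope_below*min(x, breakpoint)
    + slope_above*max(x - breakpoint, 0)`` — continuous at the breakpoint
    by construction.
    """

    intercept: float
    slope_below: float
    slope_above: float
    breakpoint: float
    sse: float
    r2: float
    n: int
    p_value_slope_change: float


@dataclass(frozen=True)
class LinearFit:
    """Simple linear regression summary (urinary N on N intake)."""

    intercept: float
    slope: float
    r2: float
    se_intercept: float
    se_slope: float
    n: int
    p_value_slope: float


@dataclass(frozen=True)
class TreatmentComparison:
    """Repeated-measures comparison of one parameter between the two
    phase-2 treatment groups: LS means, pooled SEM and the treatment
    p-value on between-cow degrees of freedom."""

    parameter: str
    lsmean_low: float
    lsmean_medium: float
    sem: float
    p_value: float
    n_cows: int
    n_days: int


@dataclass(frozen=True)
class SkewnessScreen:
    """Result of the normality (skewness) screen."""

    skewness: float
    flagged: bool
    threshold: float = 1.0
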