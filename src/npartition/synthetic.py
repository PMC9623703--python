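"""Synthetic cow-day data for the two experimental phases.

Phase 1 emulates the 21-day grazing acclimation: three treatment groups
(0, 351 and 690 g urea/d) ramped up in the stepped schedule the ethics
protocol required, with milk yield responding to the daily urea dose through
a continuous two-segment (broken-stick) model plus cow-level and residual
Gaussian noise.

Phase 2 emulates the metabolism-stall total-collection week: ten cows on
0 or 250 g urea/d, seven days each. For every cow-day the generator draws
intake covariates, computes the true N intake, places total non-urinary N so
that the implied urinary N (intake minus fecal minus milk N) follows the
configured linear function of N intake, and back-solves fecal N
concentration and milk CP % so that the balance module recovers those values
exactly.
"""
from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np

from .config import Distribution, SimulationConfig
from .errors import ImplausibleValueWarning, InvalidArgumentError
from .types import (
    CowDayRecord,
    CowProfile,
    MilkRecord,
    PastureComposition,
    StallDayRecord,
    Treatment,
    UreaScheduleEntry,
)

#: Printed acclimation ramp for the top (690 g/d) treatment:
#: (total g/d, number of days). Lower final doses reuse the leading steps.
RAMP_STEPS: tuple[tuple[float, int], ...] = (
    (88.0, 4), (176.0, 3), (351.0, 4), (450.0, 3), (600.0, 4), (690.0, 3),
)
_RAMP_DURATIONS = (4, 3, 4, 3, 4, 3)

#: Length of the acclimation window in days.
ACCLIMATION_DAYS = 21

#: Doses at or above this (g/d) are split into 3 feedings, else 2.
THREE_DOSE_THRESHOLD = 351.0


def _doses_per_day(total: float) -> int:
    return 3 if total >= THREE_DOSE_THRESHOLD else 2


def build_acclimation_schedule(
    treatment: Treatment, final_dose: float
) -> list[UreaScheduleEntry]:
    """Stepped urea ramp for one treatment, covering the 21-day window.

    The printed step doses below ``final_dose`` are reused and the ramp ends
    on ``final_dose`` itself; step durations follow the printed 4/3/4/3/4/3-day
    pattern. A group whose ramp is shorter than the window starts later
    (zero dose until then) so that all groups finish the window on their
    final dose — the medium-N group's first non-zero dose falls on day 11.

    Parameters
    ----------
    treatment : group label, recorded on the entries' behalf only.
    final_dose : target total dose in g/d; 0 yields a single zero entry.
    """
    if final_dose < 0:
        raise InvalidArgumentError(f"final_dose must be >= 0, got {final_dose}")
    if final_dose == 0:
        return [UreaScheduleEntry(1, ACCLIMATION_DAYS, 0.0, 2)]

    doses = [d for d, _ in RAMP_STEPS if d < final_dose] + [float(final_dose)]
    durations = [_RAMP_DURATIONS[i % len(_RAMP_DURATIONS)] for i in range(len(doses))]
    ramp_days = sum(durations)
    start = max(1, ACCLIMATION_DAYS - ramp_days + 1)

    entries: list[UreaScheduleEntry] = []
    if start > 1:
        entries.append(UreaScheduleEntry(1, start - 1, 0.0, 2))
    day = start
    for dose, ndays in zip(doses, durations):
        k = _doses_per_day(dose)
        entries.append(UreaScheduleEntry(day, ndays, dose / k, k))
        day += ndays
    return entries


def dose_on_day(schedule: Sequence[UreaScheduleEntry], day: int) -> float:
    """Total urea dose (g/d) in effect on 1-based ``day``; the final entry's
    dose persists past the window."""
    if day < 1:
        raise InvalidArgumentError("day is 1-based")
    for entry in schedule:
        if entry.start_day <= day <= entry.end_day:
            return entry.total_g_per_day
    return schedule[-1].total_g_per_day


def predict_true_milk(urea_g: float, splitline: tuple[float, float, float, float]) -> float:
    """Evaluate the generator's true broken-stick milk-yield model."""
    a, b_lo, b_hi, bp = splitline
    return a + b_lo * min(urea_g, bp) + b_hi * max(urea_g - bp, 0.0)


def _draw(rng: np.random.Generator, dist: Distribution) -> float:
    return float(rng.normal(dist.mean, dist.sd)) if dist.sd > 0 else dist.mean


def _draw_pasture(rng: np.random.Generator, dists) -> PastureComposition:
    return PastureComposition(
        cp_pct=min(max(_draw(rng, dists.cp_pct), 0.0), 100.0),
        ndf_pct=min(max(_draw(rng, dists.ndf_pct), 0.0), 100.0),
        adf_pct=min(max(_draw(rng, dists.adf_pct), 0.0), 100.0),
        nsc_pct=min(max(_draw(rng, dists.nsc_pct), 0.0), 100.0),
        dmd_pct=min(max(_draw(rng, dists.dmd_pct), 0.0), 100.0),
        me=max(_draw(rng, dists.me), 1e-6),
    )


def build_cow_profiles(
    config: SimulationConfig,
    rng: np.random.Generator,
    treatments: Sequence[Treatment],
) -> list[CowProfile]:
    """Draw one herd: ``n_cows_per_treatment`` cows per listed treatment,
    with herd-level trait distributions and mean-zero random intercepts."""
    profiles = []
    i = 0
    for trt in treatments:
        for _ in range(config.n_cows_per_treatment):
            i += 1
            profiles.append(
                CowProfile(
                    cow_id=f"cow{i:03d}",
                    parity=int(rng.integers(2, 7)),
                    dim=max(1, int(round(rng.normal(config.dim_mean, config.dim_sd)))),
                    bw=max(1.0, float(rng.normal(config.bw_mean, config.bw_sd))),
                    bcs=float(np.clip(rng.normal(config.bcs_mean, config.bcs_sd), 1.01, 9.99)),
                    treatment=trt,
                    cow_intercept_milk=(
                        float(rng.normal(0.0, config.cow_sd_milk))
                        if config.cow_sd_milk > 0 else 0.0
                    ),
                    cow_intercept_urinen=(
                        float(rng.normal(0.0, config.cow_sd_urine))
                        if config.cow_sd_urine > 0 else 0.0
                    ),
                )
            )
    return profiles


#: Final phase-1 dose by treatment (g urea/d).
PHASE1_FINAL_DOSE = {
    Treatment.LOW_N: 0.0,
    Treatment.MEDIUM_N: 351.0,
    Treatment.HIGH_N: 690.0,
}


def simulate_phase1(config: SimulationConfig) -> list[CowDayRecord]:
    """Generate the grazing-phase cow-day records.

    Milk yield per cow-day is the true broken-stick response to that day's
    urea dose plus the cow's random intercept plus residual noise. Records
    are reproducible: equal seeds give identical collections.
    """
    rng = np.random.default_rng(config.seed)
    profiles = build_cow_profiles(
        config, rng, (Treatment.LOW_N, Treatment.MEDIUM_N, Treatment.HIGH_N)
    )
    schedules = {
        trt: build_acclimation_schedule(trt, dose)
        for trt, dose in PHASE1_FINAL_DOSE.items()
    }
    records: list[CowDayRecord] = []
    for cow in profiles:
        schedule = schedules[cow.treatment]
        for day in range(1, config.n_days_phase1 + 1):
            urea = dose_on_day(schedule, day)
            mu = predict_true_milk(urea, config.true_splitline)
            eps = rng.normal(0.0, config.noise_sd_milk) if config.noise_sd_milk > 0 else 0.0
            milk_yield = max(0.0, mu + cow.cow_intercept_milk + eps)
            milk = MilkRecord(
                yield_kg=milk_yield,
                fat_pct=float(np.clip(_draw(rng, config.milk_fat), 0, 15)),
                cp_pct=float(np.clip(_draw(rng, config.phase1_milk_cp), 0, 15)),
                lactose_pct=float(np.clip(_draw(rng, config.milk_lactose), 0, 15)),
            )
            records.append(
                CowDayRecord(
                    cow_id=cow.cow_id,
                    day=day,
                    treatment=cow.treatment,
                    urea_g=urea,
                    milk=milk,
                    bw=cow.bw,
                    km_walked=max(0.0, _draw(rng, config.km_walked)),
                    pasture=_draw_pasture(rng, config.pasture_phase1),
                )
            )
    return records


#: First and last day (1-based, continuing the phase-1 count) of the
#: total-collection week.
COLLECTION_FIRST_DAY = 25


def simulate_phase2(config: SimulationConfig) -> list[StallDayRecord]:
    """Generate the metabolism-stall total-collection records.

    Construction guarantees that pushing these records through the N-balance
    module yields urinary N = intercept + slope x N intake + noise, where
    (intercept, slope) is ``config.true_urine_line``: total non-urinary N is
    set to intake minus that target and split into fecal vs milk N by
    ``nonurine_split_fecal``; fecal N concentration and milk CP % are then
    back-solved from the drawn fecal mass and milk yield.

    A urine target that exceeds intake (possible only at degenerately low
    intake) is clipped to keep components non-negative, with a warning.
    """
    rng = np.random.default_rng(config.seed + 1_000_000)
    profiles = build_cow_profiles(config, rng, (Treatment.LOW_N, Treatment.MEDIUM_N))
    a, slope = config.true_urine_line
    f_fecal = config.nonurine_split_fecal

    records: list[StallDayRecord] = []
    for cow in profiles:
        urea = 0.0 if cow.treatment is Treatment.LOW_N else config.phase2_urea_g
        base_yield = (
            config.phase2_milk_yield_low
            if cow.treatment is Treatment.LOW_N
            else config.phase2_milk_yield_medium
        )
        for day in range(
            COLLECTION_FIRST_DAY, COLLECTION_FIRST_DAY + config.n_days_phase2
        ):
            offered = config.offered_kg_dm
            refused = float(np.clip(_draw(rng, config.refused_kg_dm), 0.0, offered))
            pasture = _draw_pasture(rng, config.pasture_phase2)
            dmi = offered - refused
            n_intake = (
                dmi * 1000.0 * (pasture.cp_pct / 100.0) / 6.25
                + urea * config.urea_n_fraction
            )

            eps = rng.normal(0.0, config.noise_sd_urine) if config.noise_sd_urine > 0 else 0.0
            urine_target = a + slope * n_intake + cow.cow_intercept_urinen + eps
            if urine_target < 0.0:
                warnings.warn(
                    f"cow {cow.cow_id} day {day}: implied urine N "
                    f"{urine_target:.1f} g/d clipped to 0",
                    ImplausibleValueWarning,
                    stacklevel=2,
                )
                urine_target = 0.0
            nonurine = n_intake - urine_target
            if nonurine < 0.0:
                warnings.warn(
                    f"cow {cow.cow_id} day {day}: implied non-urinary N "
                    f"{nonurine:.1f} g/d clipped to 0",
                    ImplausibleValueWarning,
                    stacklevel=2,
                )
                nonurine = 0.0
            fecal_n = f_fecal * nonurine
            milk_n = (1.0 - f_fecal) * nonurine

            eps_m = rng.normal(0.0, config.noise_sd_milk) if config.noise_sd_milk > 0 else 0.0
            milk_yield = max(1e-6, base_yield + cow.cow_intercept_milk + eps_m)
            # back-solve composition so the balance module recovers milk_n
            milk_cp = float(np.clip(milk_n * 6.38 / (milk_yield * 10.0), 0.0, 15.0))
            milk = MilkRecord(
                yield_kg=milk_yield,
                fat_pct=float(np.clip(_draw(rng, config.milk_fat), 0, 15)),
                cp_pct=milk_cp,
                lactose_pct=float(np.clip(_draw(rng, config.milk_lactose), 0, 15)),
            )

            fecal_wet = max(1e-6, _draw(rng, config.fecal_wet_kg))
            records.append(
                StallDayRecord(
                    cow_id=cow.cow_id,
                    day=day,
                    treatment=cow.treatment,
                    offered_kg_dm=offered,
                    refused_kg_dm=refused,
                    urea_g=urea,
                    milk=milk,
                    fecal_wet_kg=fecal_wet,
                    fecal_dm_pct=float(np.clip(_draw(rng, config.fecal_dm_pct), 1, 100)),
                    fecal_n_g_per_kg=fecal_n / fecal_wet,
                    pasture=pasture,
                    urine_volume_l=max(1.0, _draw(rng, config.urine_volume_l)),
                )
            )
    return records
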