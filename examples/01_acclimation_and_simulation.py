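"""Build the urea acclimation schedules and simulate the grazing phase.

Cows are ramped onto their final urea dose over a 21-day window; the
medium-N group starts on day 11 so all groups finish the window on their
final dose. Milk yield responds to the daily dose through a broken-stick
model: flat-to-rising below ~350 g/d, declining above it.
"""
import npartition as nv

for trt, dose in nv.PHASE1_FINAL_DOSE.items():
    sched = nv.build_acclimation_schedule(trt, dose)
    steps = ", ".join(
        f"d{e.start_day}-{e.end_day}: {e.total_g_per_day:g} g/d"
        + (f" ({e.grams_per_dose:g} g x{e.doses_per_day})" if e.total_g_per_day else "")
        for e in sched
    )
    print(f"{trt.value:>9}: {steps}")

records = nv.simulate_phase1(nv.SimulationConfig(seed=1))
print(f"\nsimulated {len(records)} cow-days "
      f"({len({r.cow_id for r in records})} cows x 21 d)")
high_last = [r for r in records if r.treatment is nv.Treatment.HIGH_N and r.day == 21]
print("high-N cows on day 21 (690 g urea/d), milk yield kg/d:",
      [round(r.milk.yield_kg, 1) for r in high_last])
print("-> doses follow each cow's schedule; yields scatter around the "
      "true response (13.5 kg/d at 690 g) by cow and day noise.")
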