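"""Back-calculate grazing-phase dry-matter intake from energy requirements.

While cows graze, intake cannot be weighed, so DMI is inferred: sum the
cow's metabolizable-energy needs (maintenance, walking, body-weight change,
milk synthesis) and divide by the pasture's ME concentration.
"""
import npartition as nv

bw = 505.0            # kg, herd mean
km = 2.0              # km walked per day to and from the paddock
bw_series = [(d, 505.0 + 0.05 * d) for d in range(0, 22, 7)]  # weekly weighings
milk = nv.MilkRecord(yield_kg=21.5, fat_pct=4.2, cp_pct=3.4, lactose_pct=4.8)

delta = nv.estimate_daily_bw_change(bw_series)
req = nv.requirement(bw=bw, km_walked=km, delta_bw=delta, milk=milk)
dmi = nv.back_calculate_dmi(req, diet_me=11.8)

print(f"maintenance : {req.maintenance_mj:6.1f} MJ/d  (0.56 x BW^0.75)")
print(f"activity    : {req.activity_mj:6.1f} MJ/d  (0.0037 x BW x km)")
print(f"BW change   : {req.bw_change_mj:6.1f} MJ/d  ({delta:+.2f} kg/d x 30 MJ/kg)")
print(f"milk        : {req.milk_mj:6.1f} MJ/d  (fat/CP/lactose energy / 0.65)")
print(f"total       : {req.total_mj:6.1f} MJ/d")
print(f"back-calculated DMI at 11.8 MJ ME/kg: {dmi:.1f} kg DM/d")
print(f"-> this cow's requirements imply she ate {dmi:.1f} kg of the "
      "20 kg DM/d allowance offered; milk synthesis dominates the budget.")
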