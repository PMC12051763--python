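"""Absorbed-dose scaling between ²²⁵Ac- and ²¹²Pb-labelled ligands.

Assuming both compounds share the biologic half-life implied by the
fitted 8.0 h effective whole-body clearance of the ²¹²Pb ligand, the
dose per administered activity scales as (chain α+β energy ratio) ×
(effective half-life ratio).
"""

from alphapk import dose_scaling

scenario = dose_scaling.ScalingScenario.from_effective_half_life(8.0)
s = dose_scaling.summary(scenario)

print(f"Shared biologic half-life: {s['biologic_half_life_h']:.1f} h")
print(f"Effective half-lives: {s['effective_half_life_a_h']:.1f} h (Ac-225) vs "
      f"{s['effective_half_life_b_h']:.1f} h (Pb-212)")
print(f"Chain α+β energy ratio: {s['chain_energy_ratio']:.2f} "
      f"(≈{round(s['chain_energy_ratio'], 1)} to one decimal)")
print(f"Time-integrated activity ratio: {s['time_integrated_activity_ratio']:.2f}")
print(f"Absorbed dose per administered MBq: {s['absorbed_dose_ratio']:.1f}× higher "
      "for the Ac-225 ligand")

eq = dose_scaling.equivalent_activity(8.0, scenario)
print(f"Dose-matching 8 MBq of the Ac-225 ligand requires ≈{eq:.0f} MBq of "
      "the Pb-212 ligand — the rationale for ~100 MBq therapy activities.")
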