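"""Predict ²¹²Pb lesion uptake from PSMA-PET SUVs and classify detectability.

Uses the bundled nine-lesion assessment table: concentrations follow
SUV_mean × decay-corrected activity / body weight (physical decay to 3 h,
62 kg for patient ID03, 80 kg default), volumes are box products of the
CT dimensions (1 cm³ when unmeasured).  Detectability is checked both
against a phantom-calibrated contrast map and the fallback threshold
rule (≥4 kBq/mL and ≥1.5 cm³).
"""

from alphapk import detectability, simulate, study

table = study.study_uptake_table()
cmap = detectability.calibrate_contrast_map(
    simulate.gen_phantom_obs(simulate.CohortSpec(seed=0, phantom_noise_sd=0.0))
)

print(f"{'patient':8} {'location':24} {'kBq/mL':>7} {'cm3':>6}  map  rule")
for e in table:
    by_map = detectability.classify_detectable(e, cmap)
    by_rule = detectability.classify_detectable(e, None)
    print(
        f"{e.patient_id:8} {e.location:24} {e.concentration_kBq_mL:7.2f} "
        f"{e.volume_cm3:6.2f}  {'Y' if by_map else 'N'}    {'Y' if by_rule else 'N'}"
    )

n = sum(detectability.classify_detectable(e, None) for e in table)
print(f"\n{n} of {len(table)} lesions detectable: only the retrocaval lymph "
      "node combines enough uptake (~5.4 kBq/mL) with enough volume.")
print(f"Minimum detectable concentration at 26 cm³: "
      f"{detectability.min_detectable_concentration(cmap, 26.0):.1f} kBq/mL "
      "(approaches the 2 kBq/mL phantom floor for large volumes).")
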