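"""Decay-chain activities and energy budget of the ²¹²Pb in-vivo α-generator.

²¹²Pb itself emits no α-particle; its daughter ²¹²Bi delivers exactly one
α per parent decay through the branched ²⁰⁸Tl / ²¹²Po routes.
"""

from alphapk import decay

chain = decay.DecayChain("Pb-212", initial_activity_MBq=9.0)

print("Activities (MBq) after a 9.0 MBq administration, no biologic clearance:")
for t in (0.0, 1.0, 4.0, 10.64, 24.0):
    acts = decay.bateman_activities(chain, t)
    print(f"  t={t:5.2f} h  " + "  ".join(f"{k}={v:.3f}" for k, v in acts.items() if v > 1e-6))

alpha = decay.total_emitted_energy(chain, ("alpha",))
total = decay.total_emitted_energy(chain, ("alpha", "beta_mean"))
print(f"\nAlpha energy per parent decay: {alpha:.2f} MeV (one α per decay)")
print(f"Alpha+beta energy per parent decay: {total:.2f} MeV")
print("At late times ²¹²Bi activity exceeds ²¹²Pb by the transient-equilibrium "
      "factor λ_Bi/(λ_Bi−λ_Pb) ≈ 1.105.")
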