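"""Plan a supersaturated drug/oligomer simulation box.

Reproduces the composition arithmetic for an anionic 13-drug box with a
PVP-VA oligomer: oligomer mass, drug:oligomer and Na+:drug mass ratios, the
supersaturation fold of a 200 mg dose in an empty stomach, salt-ion counts
for ~0.01 M, and electroneutral ion totals, then writes the initial drug
centres by seeded random insertion.
"""

import numpy as np

from assdkit.formulation import (
    DoseScenario,
    counterion_mass_ratio,
    drug_oligomer_mass_ratio,
    oligomer_mass,
    plan_box,
    pvpva_34mer,
    random_insertion,
    supersaturation_ratio,
)

olig = pvpva_34mer()
m_olig = oligomer_mass(olig)
print(f"PVP-VA 34-mer mass: {m_olig:.1f} Da")
print(f"drug:oligomer mass ratio (13 drugs): {drug_oligomer_mass_ratio(13, 381.3, m_olig).as_one_to()}")
print(f"Na+:drug mass ratio: {counterion_mass_ratio(22.99, 381.3):.4f}:1")

fold = supersaturation_ratio(DoseScenario(dose=200.0, fluid_volume=35.0,
                                          equilibrium_solubility=3.46))
print(f"supersaturation fold of the dose scenario: {float(f'{fold:.3g}'):g}")

plan = plan_box((112.0,) * 3, n_drug=13, drug_state="anionic",
                oligomer=None, molarity=0.01)
print(f"box plan: {plan.to_dict()}")
print("  (n_Na = 13 neutralizing + salt pairs; the box is electroneutral)")

centres = random_insertion(13, (112.0,) * 3, min_separation=10.0, seed=7)
d_min = min(
    np.linalg.norm((a - b) - 112.0 * np.round((a - b) / 112.0))
    for i, a in enumerate(centres) for b in centres[:i]
)
print(f"13 random centres placed; smallest periodic distance {d_min:.1f} A (>= 10 A)")
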