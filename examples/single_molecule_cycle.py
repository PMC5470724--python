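"""Single-molecule cycle at a glance: occupancies, velocity, stall.

Evaluates the five-state cross-bridge cycle of myosin Ic with the
packaged parameters under physiological nucleotides (1 mM ATP, 10 uM
ADP, 1 mM Pi) and 100 uM actin.
"""

import numpy as np

from myo1c import (Conditions, table1_parameters, transition_rates,
                   steady_state, occupancy_summaries, effective_velocity,
                   stall_force, dominance_crossing_force, gibbs_free_energy)

params = table1_parameters()
cond = Conditions.physiological(actin=100.0)

dmu = gibbs_free_energy(params, cond)
print(f"ATP hydrolysis free energy: {dmu / params.kBT:.1f} kBT")

for F in (0.0, 1.5, 4.0):
    dist = steady_state(transition_rates(params, cond.with_force(F)))
    p_sb, p_on = occupancy_summaries(dist)
    print(f"F = {F:3.1f} pN: P1..P5 = {np.round(dist.p, 3)}  "
          f"P_sb = {p_sb:.3f}  P_on = {p_on:.3f}")

v0 = effective_velocity(params, cond)
fs = stall_force(params, cond)
fc = dominance_crossing_force(params, cond)
print(f"effective velocity at zero load: {v0:.2f} nm/s")
print(f"stall force: {fs:.1f} pN (velocity changes sign here)")
print(f"ADP-state/ATP-state occupancy crossover: {fc:.2f} pN")
print("Below the crossover the cycle is limited by ADP release, above it "
      "the head is trapped in the ATP state by the catch bond.")
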