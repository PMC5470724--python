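"""Gliding of elastically coupled myosin Ic heads (Gillespie simulation).

Simulates heads that each follow the five-state cycle, coupled through
individual springs to a rigid backbone, at saturating ATP with trace
ADP/Pi.  The backbone drift rate is the motility speed.  A short 50-head
run keeps this example quick; 200 heads reproduce the ~25 nm/s scale of
membrane-coupled motility assays.
"""

from myo1c import (Conditions, table1_parameters, SimulationConfig,
                   motility_velocity)

params = table1_parameters()
cond = Conditions(atp=1000.0, adp=0.1, pi=0.1, actin=100.0)
cfg = SimulationConfig(N=50, params=params, conditions=cond,
                       mode="motility", t_max=6.0, burn_in=1.0, seed=1)
v, se, traj = motility_velocity(cfg)

print(f"heads: {cfg.N}, simulated time: {traj.t_end:.0f} s, "
      f"events: {traj.n_events}")
print(f"mean bound heads: {traj.mean_n:.1f}")
print(f"motility speed: {v:.1f} +- {se:.1f} nm/s (bootstrap SE)")
print("Each power stroke pulls the backbone forward against the drag of "
      "the other bound heads; tens of nm/s is the expected scale for "
      "this slow, high-duty-ratio motor.")
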