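"""Elasticity and Ca2+-triggered release of a myosin Ic cluster.

Uses the cooperative birth-death ensemble (load shared by the bound
heads) at physiological nucleotides and saturating actin (1 mM) to
compute the mean number of bound heads, the ensemble extension, and the
mechanical release when Ca2+ reduces binding and/or stiffness — the
candidate mechanism of fast adaptation in hair cells.
"""

from myo1c import (Conditions, table1_parameters, ensemble_from_cycle,
                   mean_bound, force_extension, calcium_release)

params = table1_parameters()
cond = Conditions.physiological(actin=1000.0)

print("force-extension of an N = 10 ensemble (kappa = 0.5 pN/nm per head):")
for F in (5.0, 10.0, 20.0):
    spec = ensemble_from_cycle(params, cond, N=10, F=F)
    print(f"  F = {F:4.0f} pN: <n> = {mean_bound(spec):5.2f} bound heads, "
          f"extension x = {force_extension(spec):4.2f} nm")

spec = ensemble_from_cycle(params, cond, N=10, F=20.0, beta=100.0)
print(f"\n100-fold binding reduction at 20 pN (N = 10): "
      f"release = {calcium_release(spec):.1f} nm")

print("\nrelease with binding/100 and stiffness/10, N = 50:")
for F in (5.0, 10.0, 20.0):
    spec = ensemble_from_cycle(params, cond, N=50, F=F, beta=100.0,
                               kappa_ca=0.05)
    print(f"  F = {F:4.0f} pN: release = {calcium_release(spec):.1f} nm")

print("\nThe large softened ensemble releases several tens of nanometres, "
      "varying far less than the fourfold change in load — the scale and "
      "weak force dependence required by the release model of fast "
      "adaptation.")
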