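"""Hydrodynamic force on a tethered particle vs syringe-pump flow rate.

Plane-Poiseuille profile in the 1 mm x 60 um channel, Stokes drag on a 1 um
particle resting at the surface.  Note the printed formulas at this geometry
give ~11.6 pN per 100 ul/min, about 2.3x the nominal 5 pN per 100 ul/min of
the measurement schedule (documented in docs/methods.md).
"""

from nanobeam import FlowChamber, force_from_flow_rate, schedule_default
from nanobeam.flow import UL_PER_MIN

chamber = FlowChamber()
print(f"{'Q (ul/min)':>10} {'force (pN)':>11}")
for q in (100, 300, 500, 700, 900, 1100, 1300):
    f = force_from_flow_rate(q * UL_PER_MIN, chamber)
    print(f"{q:>10} {f:>11.1f}")

sched = schedule_default()
print(f"\nforce schedule: {len(sched.steps)} forward steps, "
      f"{sched.steps[0][0]:.0f} -> {sched.steps[-1][0]:.0f} pN, "
      f"{sched.forward_duration_s:.0f} s, then "
      f"{len(sched.reverse_steps)} reversed steps for the symmetry check")
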