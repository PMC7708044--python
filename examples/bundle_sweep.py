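"""Axial stiffness of multi-helix bundles vs helix count.

Sweeps 2-16 helix bundles on honeycomb and square packings at fixed
per-helix densities (1 junction participation and 0.5 nicks per 21 bp)
using the calibrated degradation factors.  The striking result: because
every crossover locally softens the helices it joins, most bundles are LESS
stiff axially than a single intact duplex — about 16 helices are needed to
recover it (normalized stiffness ~1).
"""

from nanobeam.workflows import run_bundle_sweep

table = run_bundle_sweep()
print(table.to_string(index=False,
                      formatters={"stiffness_pN": "{:.1f}".format,
                                  "normalized": "{:.3f}".format}))
n16 = table[table.n_helices == 16]["normalized"]
print(f"\n16-helix bundles reach {n16.min():.2f}-{n16.max():.2f} x the "
      "stiffness of one intact B-DNA duplex.")
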