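"""Calibrate the HJ/nick degradation factors and predict construct stiffness.

Fits alpha so the two-helix ligated construct with 21 bp crossover spacing
(C170L) reproduces its mean measured stiffness of 181 pN, then beta on the
nicked counterpart (C170N, 108 pN), and finally predicts the constructs the
calibration never saw.
"""

from nanobeam import MEASURED, apparent_stiffness, calibrate_default, preset

calib = calibrate_default()
print(f"alpha = {calib.alpha:.4f}  (CI {calib.alpha_ci[0]:.4f}"
      f"..{calib.alpha_ci[1]:.4f})")
print(f"beta  = {calib.beta:.4f}  (CI {calib.beta_ci[0]:.4f}"
      f"..{calib.beta_ci[1]:.4f})")
print()
print(f"{'construct':<8} {'model K (pN)':>12} {'measured (pN)':>14}")
for name in ("C85L", "C85N", "C170L", "C170N", "6HB", "10HB"):
    k = apparent_stiffness(preset(name), calib.material).apparent_stiffness
    m = MEASURED[name]
    sd = f" +/- {m.sd_pN:.0f}" if m.sd_pN else ""
    print(f"{name:<8} {k:>12.1f} {m.mean_pN:>9.0f}{sd}")

print()
print("Both degradation factors are ~2 orders of magnitude below 1: the few")
print("bp at a crossover or nick are locally far softer than intact duplex,")
print("which is why adding helices/junctions can *reduce* axial stiffness.")
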