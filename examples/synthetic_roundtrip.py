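"""Validate the measurement pipeline on synthetic tethered-particle data.

Generates worm-like-chain trajectories under the step-wise 5..65 pN force
schedule at the model stiffness of each construct (ground truth known),
runs the symmetric-reversal QC and the slope-fit extraction, and reports
how well the true stiffness and the construct ordering are recovered.
"""

import json

from nanobeam.workflows import RunConfig, run_synthetic_roundtrip

report = run_synthetic_roundtrip(RunConfig(roundtrip_n_seeds=50, seed=0))
for row in report["per_construct"]:
    print(f"{row['construct']:<6} true {row['K_true_pN']:7.1f} pN   "
          f"recovered median {row['median_recovered_pN']:7.1f} pN   "
          f"median |err| {100 * row['median_rel_error']:4.1f}%   "
          f"QC pass {100 * row['qc_pass_rate']:.0f}%")
print(f"\nstiffness ordering preserved in "
      f"{100 * report['ordering_preserved_rate']:.0f}% of seeds")
print(f"QC: passes {100 * report['qc_good_pass_rate']:.0f}% of good tethers, "
      f"rejects {100 * report['qc_bad_reject_rate']:.0f}% of bad ones "
      "(reversal asymmetry 0.5)")
print("\nRecovery errors of a few percent reflect the residual worm-like-")
print("chain curvature above 15 pN, not noise: the extraction's linear fit")
print("slightly underestimates steep (stiff) tethers.")
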