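# Methods

## The mechanical model

A DNA origami nanobeam is modelled as `N` parallel double helices, each a
chain of base-pair axial spring elements of stiffness `k = EA / h`, with
stretch modulus `EA = 1100 pN` (the standard coarse-grained value for
B-form DNA) and rise `h = 0.34 nm/bp`. Two kinds of structural defects
locally degrade the axial stiffness:

* **Holliday junctions (crossovers).** Each junction rigidly couples the two
  helices it joins at its axial position (modelled as an exact equal-
  displacement constraint) and degrades a block of `n_hj = 5` contiguous
  elements on *each* participating helix to `alpha * k`.
* **Nicks.** A backbone discontinuity degrades `n_nick = 1` element to
  `beta * k`.

Rigid end plates gather all helices at both termini; one plate is fixed and
an axial force `F` is applied to the other. The constrained linear
equilibrium is solved exactly: rigid ties are eliminated by union-find DOF
merging (no Lagrange multipliers, constraints exact to machine precision)
and the reduced sparse stiffness matrix is factorized directly. The model is
linear, so the force–extension curve is a line through the origin and the
apparent axial stiffness

    K = (dF/d delta) * L0        [pN]

is evaluated from a single solve at a 20 pN reference force (recorded for
provenance; any force gives the same K). For a single intact helix K = EA
for any length, and for N intact end-tied helices K = N * EA — both used as
machine-precision unit checks.

**Degrees of freedom.** Only axial displacements are modelled. For straight
parallel-helix beams under pure end tension, bending and torsion contribute
negligibly; with that restriction the full 3-D frame problem reduces
exactly to this axial network. Bending response, persistence length, and
force regimes beyond the linear enthalpic one (overstretching) are out of
scope.

## Homogenized oracle

For periodic designs the network has a closed form. Per 21 bp repeat and per
helix, with `j` junction participations and `nu` nicks, the compliance in
intact-element units is

    C_rep = (21 - n_hj*j - n_nick*nu) + n_hj*j/alpha + n_nick*nu/beta

and `K = N * EA * 21 / C_rep`. The network solver and this formula are
developed independently and compared in the tests: they agree to <2% on
construct-scale beams (the residual is the end effect — the discrete
junction count vs the continuum density) and to <0.5% when the beam length
is ~200+ exact repeats.

## Design conventions

Design positions are 0-based bp indices; the element "centered" on position
`p` is element `p` (block `p - span//2 .. p - span//2 + span - 1`).

* **Two-helix DX beams.** Crossovers at multiples of the spacing `s`,
  keeping sites whose trailing segment is at least `s/2`. At 3600 bp per
  helix (1224 nm, half the M13mp18 scaffold folded back) this gives exactly
  170 crossovers at `s = 21` and 85 at `s = 42`, matching the published
  counts. Nicked variants carry one nick per helix at the midpoint of the
  interval after each crossover, in both helices at the same axial position
  (340 and 170 nicks).
* **Bundles.** Junction participations are distributed over the interfaces
  of the packing's adjacency graph — a closed ring for honeycomb cross-
  sections, a near-square grid for square packing — with per-interface
  quotas from a greedy b-matching targeting the requested per-helix density,
  phases staggered by a proper edge coloring, and a local repair pass
  enforcing a 5 bp per-helix minimum gap. On interface graphs where uniform
  per-helix density is infeasible (bipartite with unequal parts, e.g. a 3x3
  grid) the total participation budget is still spent, so the bundle-average
  density is preserved. Axial stiffness depends only on the per-helix
  counts, not the phases, so these scheduling details are inert — verified
  by the oracle-equivalence tests.

## Calibration

`alpha` is fitted first so the simulated K of the ligated 21 bp-spacing
construct (C170L) equals its mean measured stiffness (181 pN); `beta` is
then fitted on the nicked counterpart (C170N, 108 pN) with `alpha` fixed.
K is strictly increasing in each factor, so each fit is bracketed
root-finding on (1e-9, 1] (Brent, relative tolerance 1e-12; residuals are
checked below 1e-6 of the target). Targets outside the attainable range
raise a range error reporting the bracket. Confidence intervals repeat the
fit at the target mean -/+ SD (`ci_mode = mean_sd`; per-replicate extrema
were not published as a table). The order is part of the procedure:
fitting beta first is not equivalent, and the API enforces ligated-first.

Results with defaults: `alpha = 0.0207` (CI 0.011–0.031), `beta = 0.0057`
(CI 0.0020–0.0226) — both two orders of magnitude below 1, i.e. the few bp
at a crossover or nick behave locally like ssDNA still in its entropic
regime rather than stiff duplex.

**Identifiability of the HJ span.** In a purely axial model, a construct's
stiffness depends on the HJ block only through the excess compliance per
junction participation, `n_hj * (1/alpha - 1)`, and calibration pins that
combination down. Consequently all predictions are *exactly invariant* to
`n_hj` under recalibration (`scripts/hj_span_scan.py` demonstrates this);
the span only rescales the fitted `alpha` itself. The default `n_hj = 5`
reflects the physical footprint of the strand-exchange region and yields
`alpha ~ 0.021`, consistent with the published fit of 0.0205; the fitted
`beta` is more topology-sensitive (published 0.009 vs 0.0057 here under a
1 bp nick element) but lies well inside the published confidence interval.
The nick span is deliberately not tuned to force agreement.

## Flow forces

The drag force on the tethered particle combines `v_max = 3Q/(2wh)`, the
parabolic profile `v(z) = 4 v_max (z/h)(1 - z/h)`, and Stokes' law
`F = 6 pi eta r v` — three linear maps, so force is linear in flow rate.
Defaults: 1 mm x 60 um channel, water viscosity 8.9e-4 Pa s, 1 um particle
with its center one radius above the surface, no Faxen wall correction (a
multiplicative correction factor is exposed, default 1).

Evaluated at this geometry the formulas give ~11.6 pN per 100 ul/min, about
2.3x the nominal 5 pN per 100 ul/min of the measurement schedule quoted for
the same apparatus. The formulas are implemented as printed and the
discrepancy is documented rather than corrected; nothing downstream depends
on the flow-to-force mapping — the force schedule (5 pN steps every 10 s up
to 65 pN, plus a reversed 5–35 pN phase) is specified directly in pN.

## Stiffness extraction

Per trajectory (displacement = |position - initial position|, 5 frames/s):

1. **QC.** Mean plateau displacement at force levels present in both flow
   directions is compared; the particle passes if the maximum relative
   mismatch is <= 0.2. Missing reverse data gives a distinct
   "not evaluable" status.
2. **Unstretched length.** `L0` = mean displacement at the 10 pN forward
   plateau (tether straightened, not yet stretched) minus the pre-flow
   baseline.
3. **Stiffness.** OLS of plateau-mean force on plateau-mean displacement
   over forward plateaus strictly above 15 pN (the enthalpic regime;
   >= 3 plateaus required), `K = slope * L0`.

Plateau means drop the first 2 s of each 10 s step (settling) and average
the rest; the original analysis does not specify per-step aggregation, so
both the settling time and the threshold are parameters.

## Synthetic data generator

Trajectories are generated from an extensible worm-like chain,

    x(F) = L0 * (1 - 1/2 sqrt(kBT/(F*Lp)) + F/K_true),

with `Lp = 100 nm` (DX-tile beams are about twice as stiff in bending as
bare dsDNA at 40–60 nm), `kBT = 4.1 pN nm`, and per-frame white Gaussian
tracking noise of 20 nm. Displacements are taken relative to the pre-flow
state, where the tether carries only a rest tension `kBT/(4 Lp)` (~0.01 pN,
the force at which the interpolation formula crosses zero extension — the
particle sits at its anchor). This reproduces the two-regime shape the
extraction assumes: entropic slack saturating below ~10 pN, linear
response above 15 pN with slope `L0/K_true`. Bad tethers scale their
reverse-phase response by an asymmetry factor (default 0.5). Cohort
randomness derives from an explicit cohort seed plus the particle index.

What the generator does *not* emulate: correlated Brownian bead motion,
drift, tether-angle geometry, bead-size variation, and the overstretching
transition. Passing recovery tests therefore validate the plateau/fit
logic, not robustness to every artifact of real tracking data.

**Expected recovery bias.** Above 15 pN the WLC term still contributes
curvature, so the linear fit slightly underestimates stiff tethers (up to
~8% at K = 334 pN) and `L0` slightly exceeds the contour length for
compliant ones. The round-trip experiment (50 seeds per construct at the
four model stiffness values) recovers medians within a few percent to ~9%,
preserves the construct ordering in every seed, and the QC separates good
from bad tethers cleanly at tolerance 0.2.

## Problem sizes and numerical choices

The measured constructs assemble to ~7,200 elements (two 3600 bp helices);
bundles in the sweep reach ~20,000. Direct sparse factorization solves
these in milliseconds, so all tests and the reproduction scripts run the
full construct sizes; the synthetic round trip uses 50 seeds per construct
and 100-particle QC cohorts. Degenerate inputs are defined, not errors,
where a physical reading exists: spacing beyond the helix length gives a
junction-free design; zero measurement SD gives a degenerate confidence
interval. Overlapping degraded blocks, out-of-range calibration targets,
and disconnected load paths raise typed errors.

## Known limitations

* Axial-only response; no bending/torsion coupling, no thermal
  fluctuations, no electrostatic inter-helix gap (negligible under the
  >15 pN analysis window).
* The bundle builder idealizes honeycomb cross-sections as interface rings;
  real lattice adjacency differs for large N, but only per-helix densities
  enter the axial result.
* `beta` trades off exactly against `n_nick`, like `alpha` against `n_hj`;
  reported point values of the factors are meaningful only together with
  their spans.
* The flow-to-force map inherits the ~2.3x formula-vs-schedule discrepancy
  noted above.
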