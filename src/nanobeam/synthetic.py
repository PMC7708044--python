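"""Ground-truth-known synthetic particle trajectories.

The generator emulates the flow-stretching measurement on a tether whose
mean extension follows the extensible worm-like chain (WLC) interpolation

    x(F) = L0 * (1 - 1/2 * sqrt(kBT / (F * Lp)) + F / K_true)

which has exactly the two regimes the measurement analysis assumes: an
entropic slack that saturates below ~10 pN and a linear enthalpic regime
above ~15 pN with slope L0 / K_true.  Displacements are measured relative
to the pre-flow position, at which the tether carries only a tiny rest
tension (default kBT / (4 Lp), the force at which the interpolated
extension crosses zero, i.e. the particle sits at the anchor).  White
Gaussian tracking noise is added per frame; the reported displacement is an
absolute value, as in particle tracking.

Badly tethered particles respond asymmetrically when the flow is reversed
(displacement scaled by ``reverse_asymmetry``), which is what the
symmetric-reversal QC is designed to reject.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

from .errors import ValidationError
from .extraction import FORWARD, PRE, REVERSE, Trajectory, sample_schedule
from .flow import ForceSchedule, schedule_default

#: Thermal energy at room temperature, pN nm.
KBT_PN_NM = 4.1


@dataclass(frozen=True)
class TetherModel:
    """Ground-truth tether parameters for trajectory synthesis.

    ``Lp`` defaults to 100 nm: DX-tile nanobeams are reported about twice as
    stiff in bending as bare dsDNA (40-60 nm persistence length).
    ``noise_sigma`` is per-frame tracking noise in nm.
    """

    K_true: float                 # apparent stretch stiffness, pN
    L0: float = 1224.0            # contour length, nm
    Lp: float = 100.0             # persistence length, nm
    kBT: float = KBT_PN_NM        # pN nm
    noise_sigma: float = 20.0     # nm
    frame_rate: float = 5.0       # frames / s
    bad_tether: bool = False
    reverse_asymmetry: float = 1.0
    rest_force: float | None = None  # pN; default kBT / (4 Lp)

    def __post_init__(self) -> None:
        if min(self.K_true, self.L0, self.Lp, self.kBT,
               self.frame_rate) <= 0:
            raise ValidationError("tether parameters must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.bad_tether and not self.reverse_asymmetry < 1:
            raise ValidationError(
                "a bad tether needs reverse_asymmetry < 1")

    @property
    def rest_force_pN(self) -> float:
        return (self.kBT / (4.0 * self.Lp) if self.rest_force is None
                else self.rest_force)


def mean_extension(model: TetherModel, force_pN: float) -> float:
    """Mean extensible-WLC extension (nm) at a stretching force (pN)."""
    if force_pN <= 0:
        raise ValidationError("force must be > 0")
    entropic = 0.5 * sqrt(model.kBT / (force_pN * model.Lp))
    return model.L0 * (1.0 - entropic + force_pN / model.K_true)


def simulate_trajectory(model: TetherModel, schedule: ForceSchedule,
                        seed, pre_duration_s: float = 5.0) -> Trajectory:
    """One synthetic displacement trajectory under a force schedule.

    Deterministic given ``seed`` (an int or a sequence of ints).  Plateau
    displacements equal ``mean_extension(F) - mean_extension(rest force)``
    (scaled by the reversal asymmetry for bad tethers in the reverse phase)
    plus Gaussian tracking noise, reported as absolute values.
    """
    time, force, phase = sample_schedule(schedule, model.frame_rate,
                                         pre_duration_s)
    x_rest = mean_extension(model, model.rest_force_pN)
    clean = np.zeros_like(force)
    for ph, f in {(int(p), float(fv)) for p, fv in zip(phase, force)}:
        if ph == PRE:
            continue
        x = mean_extension(model, f) - x_rest
        if ph == REVERSE and model.bad_tether:
            x *= model.reverse_asymmetry
        clean[(phase == ph) & (force == f)] = x
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, model.noise_sigma, size=clean.size) \
        if model.noise_sigma > 0 else 0.0
    return Trajectory(time=time, displacement=np.abs(clean + noise),
                      force=force, phase=phase)


def generate_cohort(n: int, K_true: float, bad_fraction: float, seed: int,
                    schedule: ForceSchedule | None = None,
                    reverse_asymmetry: float = 0.5,
                    **model_kwargs):
    """A mixed cohort of good and bad tethers with a ground-truth sidecar.

    The first ``round(n * bad_fraction)`` particles are bad tethers with the
    given reversal asymmetry.  Per-particle randomness derives from the
    cohort seed plus the particle index, so cohorts are reproducible and
    particles independent.

    Returns ``(trajectories, ground_truth)`` where ``ground_truth`` is a
    list of dicts ``{seed, particle, K_true, L0, bad_tether}``.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    if not 0 <= bad_fraction <= 1:
        raise ValidationError("bad_fraction must be in [0, 1]")
    schedule = schedule or schedule_default()
    n_bad = int(round(n * bad_fraction))
    trajectories, truth = [], []
    for i in range(n):
        bad = i < n_bad
        model = TetherModel(K_true=K_true, bad_tether=bad,
                            reverse_asymmetry=reverse_asymmetry if bad else 1.0,
                            **model_kwargs)
        trajectories.append(simulate_trajectory(model, schedule, (seed, i)))
        truth.append({"seed": seed, "particle": i, "K_true": K_true,
                      "L0": model.L0, "bad_tether": bad})
    return trajectories, truth
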