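"""Hydrodynamic force model for flow-stretching in a shallow channel.

A tethered micron-sized particle in a plane-Poiseuille flow experiences a
Stokes drag ``F = 6 pi eta r v(z)`` where the velocity profile across the
channel height is ``v(z) = 4 v_max (z/h)(1 - z/h)`` with
``v_max = 3 Q / (2 w h)`` for volumetric rate Q, width w and height h.

All core functions take SI units; forces are returned in pN.  The particle
center height defaults to one radius (particle resting on the tethering
surface); no wall (Faxen) correction is applied by default — the measurement
analysis uses unmodified Stokes' law — but a multiplicative correction
factor is exposed.

Note: evaluating these formulas at the nominal channel geometry
(1 mm x 0.06 mm) and flow rates of 100-1300 ul/min yields ~11-150 pN, about
2.3x the 5-65 pN schedule quoted for the same rates in the source
measurement description.  The formulas are implemented as printed; the force
schedule below is defined directly in pN and does not depend on this
mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi

from .errors import ValidationError

#: SI conversion: 1 ul/min in m^3/s.
UL_PER_MIN = 1e-9 / 60.0
_N_TO_PN = 1e12


@dataclass(frozen=True)
class FlowChamber:
    """Shallow rectangular flow channel plus particle geometry (SI units)."""

    width_m: float = 1e-3
    height_m: float = 6e-5
    length_m: float = 15e-3          # informational
    viscosity_pa_s: float = 8.9e-4   # water near room temperature
    particle_radius_m: float = 0.5e-6
    particle_height_m: float | None = None  # default: one radius
    wall_correction: float = 1.0

    def __post_init__(self) -> None:
        if min(self.width_m, self.height_m, self.viscosity_pa_s,
               self.particle_radius_m) <= 0:
            raise ValidationError("chamber dimensions must be positive")
        if self.particle_radius_m >= self.height_m / 2:
            raise ValidationError("particle radius must be < h/2")
        z = self.z_m
        if not 0 < z < self.height_m:
            raise ValidationError("particle height must be inside the channel")

    @property
    def z_m(self) -> float:
        return (self.particle_radius_m if self.particle_height_m is None
                else self.particle_height_m)


def v_max(Q_m3_s: float, width_m: float, height_m: float) -> float:
    """Peak velocity of the parabolic profile, ``3Q / (2wh)`` (m/s)."""
    if Q_m3_s < 0 or width_m <= 0 or height_m <= 0:
        raise ValidationError("v_max arguments must be positive (Q >= 0)")
    return 3.0 * Q_m3_s / (2.0 * width_m * height_m)


def velocity_at(z_m: float, vmax_m_s: float, height_m: float) -> float:
    """Parabolic (plane-Poiseuille) velocity at height z: no slip at the
    walls, maximum vmax at mid-height."""
    if not 0 <= z_m <= height_m:
        raise ValidationError("z outside the channel")
    zh = z_m / height_m
    return 4.0 * vmax_m_s * zh * (1.0 - zh)


def stokes_force(eta_pa_s: float, radius_m: float, v_m_s: float) -> float:
    """Stokes drag ``6 pi eta r v`` on a sphere, in pN."""
    if eta_pa_s < 0 or radius_m < 0 or v_m_s < 0:
        raise ValidationError("stokes_force arguments must be >= 0")
    return 6.0 * pi * eta_pa_s * radius_m * v_m_s * _N_TO_PN


def force_from_flow_rate(Q_m3_s: float,
                         chamber: FlowChamber | None = None) -> float:
    """Drag force (pN) on the tethered particle at volumetric rate Q.

    Composition of the three maps above; linear in Q at fixed geometry.
    """
    chamber = chamber or FlowChamber()
    vm = v_max(Q_m3_s, chamber.width_m, chamber.height_m)
    v = velocity_at(chamber.z_m, vm, chamber.height_m)
    return chamber.wall_correction * stokes_force(
        chamber.viscosity_pa_s, chamber.particle_radius_m, v)


@dataclass(frozen=True)
class ForceSchedule:
    """Step-wise force protocol: forward ramp plus a reversed-flow QC phase.

    ``steps`` and ``reverse_steps`` are lists of (force pN, duration s).
    Forward forces must be positive and non-decreasing.
    """

    steps: tuple[tuple[float, float], ...]
    reverse_steps: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValidationError("schedule needs at least one step")
        forces = [f for f, _ in self.steps]
        if min(forces) <= 0 or any(b < a for a, b in zip(forces, forces[1:])):
            raise ValidationError(
                "forward forces must be positive and non-decreasing")
        if any(d <= 0 for _, d in self.steps + self.reverse_steps):
            raise ValidationError("step durations must be positive")
        object.__setattr__(self, "steps", tuple(map(tuple, self.steps)))
        object.__setattr__(self, "reverse_steps",
                           tuple(map(tuple, self.reverse_steps)))

    @property
    def forward_duration_s(self) -> float:
        return sum(d for _, d in self.steps)

    @property
    def total_duration_s(self) -> float:
        return self.forward_duration_s + sum(d for _, d in self.reverse_steps)


def schedule_default() -> ForceSchedule:
    """The measurement protocol: 5 pN start, +5 pN every 10 s up to 65 pN
    (13 forward steps, 130 s), then a reversed-flow phase 5..35 pN for the
    symmetric-reversal quality check."""
    forward = tuple((5.0 * i, 10.0) for i in range(1, 14))
    reverse = tuple((5.0 * i, 10.0) for i in range(1, 8))
    return ForceSchedule(steps=forward, reverse_steps=reverse)
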