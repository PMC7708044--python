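"""Two-step calibration of the local degradation factors alpha and beta.

The HJ factor ``alpha`` is fitted first so that the simulated apparent
stiffness of a ligated construct (junctions, no nicks) matches its mean
measured stiffness; ``beta`` is then fitted on the nicked counterpart with
``alpha`` held fixed.  Both fits are monotone one-dimensional root-finding
problems: apparent stiffness is strictly increasing in each factor, so the
root is unique and is found by bracketed root-finding on (1e-9, 1].

Confidence intervals are propagated by repeating the fit at the target's
mean -/+ SD.  The order matters and is fixed by the procedure: fitting beta
before alpha is not equivalent (the ligated construct constrains alpha
alone; the nicked one constrains the alpha/beta combination).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import pandas as pd
from scipy.optimize import brentq

from .designs import NanobeamDesign, preset
from .errors import CalibrationRangeError, ValidationError
from .measurements import MEASURED, MeasuredStiffness
from .mechanics import MaterialParams, apparent_stiffness

_BRACKET_LO = 1e-9
_REL_TOL = 1e-12


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted degradation factors with confidence intervals."""

    alpha: float
    beta: float
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    targets_used: dict[str, float]
    residuals: dict[str, float]
    material: MaterialParams = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "beta": self.beta,
            "alpha_ci": list(self.alpha_ci), "beta_ci": list(self.beta_ci),
            "targets_used": self.targets_used, "residuals": self.residuals,
            "EA_pN": self.material.EA, "n_hj": self.material.n_hj,
            "n_nick": self.material.n_nick,
        }


def _fit_factor(target_K: float, k_of: Callable[[float], float],
                name: str) -> float:
    """Root of K(factor) = target_K on (0, 1] by bracketed root-finding."""
    k_lo = k_of(_BRACKET_LO)
    k_hi = k_of(1.0)
    if not k_lo < target_K <= k_hi:
        raise CalibrationRangeError(
            f"target {target_K} pN outside attainable {name} range "
            f"({k_lo:.3g}, {k_hi:.3g}] pN")
    if target_K == k_hi:
        return 1.0
    root = brentq(lambda x: k_of(x) - target_K, _BRACKET_LO, 1.0,
                  rtol=_REL_TOL, maxiter=200)
    return float(root)


def calibrate_alpha(target_K: float, design: NanobeamDesign,
                    material: MaterialParams) -> float:
    """Fit the HJ factor alpha on a ligated (nick-free) design."""
    if design.n_junctions == 0:
        raise ValidationError("alpha calibration needs a design with junctions")
    if design.n_nicks > 0:
        raise ValidationError(
            "alpha calibration requires a ligated (nick-free) design")
    return _fit_factor(
        target_K,
        lambda a: apparent_stiffness(
            design, material.with_factors(alpha=a)).apparent_stiffness,
        "alpha")


def calibrate_beta(target_K: float, design: NanobeamDesign,
                   material: MaterialParams, alpha: float) -> float:
    """Fit the nick factor beta with alpha held fixed."""
    if design.n_nicks == 0:
        raise ValidationError("beta calibration needs a design with nicks")
    return _fit_factor(
        target_K,
        lambda b: apparent_stiffness(
            design, material.with_factors(alpha=alpha, beta=b)
        ).apparent_stiffness,
        "beta")


def confidence_interval(mean_K: float, sd_K: float,
                        fit: Callable[[float], float]
                        ) -> tuple[float, float]:
    """Fit at mean -/+ SD: the monotone map sends the spread of the target
    to an interval for the factor."""
    if sd_K < 0:
        raise ValidationError("sd must be >= 0")
    lo = fit(mean_K - sd_K)
    hi = fit(mean_K + sd_K)
    return (min(lo, hi), max(lo, hi))


def calibrate_two_step(ligated: NanobeamDesign, nicked: NanobeamDesign,
                       material: MaterialParams,
                       ligated_target: MeasuredStiffness,
                       nicked_target: MeasuredStiffness) -> CalibrationResult:
    """Full pipeline: alpha from the ligated construct, then beta from the
    nicked one, with confidence intervals from the measurement spread."""
    alpha = calibrate_alpha(ligated_target.mean_pN, ligated, material)
    beta = calibrate_beta(nicked_target.mean_pN, nicked, material, alpha)
    alpha_ci = confidence_interval(
        ligated_target.mean_pN, ligated_target.sd_pN or 0.0,
        lambda t: calibrate_alpha(t, ligated, material))
    beta_ci = confidence_interval(
        nicked_target.mean_pN, nicked_target.sd_pN or 0.0,
        lambda t: calibrate_beta(t, nicked, material, alpha))
    fitted = material.with_factors(alpha=alpha, beta=beta)
    residuals = {
        ligated.name or "ligated":
            apparent_stiffness(ligated, fitted).apparent_stiffness
            - ligated_target.mean_pN,
        nicked.name or "nicked":
            apparent_stiffness(nicked, fitted).apparent_stiffness
            - nicked_target.mean_pN,
    }
    return CalibrationResult(
        alpha=alpha, beta=beta, alpha_ci=alpha_ci, beta_ci=beta_ci,
        targets_used={ligated.name or "ligated": ligated_target.mean_pN,
                      nicked.name or "nicked": nicked_target.mean_pN},
        residuals=residuals, material=fitted)


def calibrate_default(material: MaterialParams | None = None
                      ) -> CalibrationResult:
    """Calibrate on the measured C170L/C170N means with default material."""
    material = material or MaterialParams()
    return calibrate_two_step(preset("C170L"), preset("C170N"), material,
                              MEASURED["C170L"], MEASURED["C170N"])


def predict_constructs(result: CalibrationResult,
                       designs: list[NanobeamDesign]) -> pd.DataFrame:
    """Model stiffness of each design under the calibrated parameters."""
    rows = []
    for d in designs:
        res = apparent_stiffness(d, result.material)
        rows.append({"construct": d.name or f"{d.n_helices}-helix",
                     "length_nm": d.length_nm,
                     "n_junctions": d.n_junctions,
                     "n_nicks": d.n_nicks,
                     "model_stiffness_pN": res.apparent_stiffness})
    return pd.DataFrame(rows)
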