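"""End-to-end reproductions: stiffness table, bundle sweep, synthetic
round trip.

Each runner is a plain function returning pandas objects; when given an
output directory it also writes CSV/JSON artifacts plus a manifest (config
hash, seed, package version) so runs can be repeated exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationResult, calibrate_two_step, predict_constructs
from .designs import preset, PRESET_NAMES
from .errors import ValidationError
from .extraction import summarize_cohort
from .flow import FlowChamber, schedule_default
from .measurements import MEASURED
from .mechanics import MaterialParams, bundle_sweep
from .synthetic import generate_cohort


@dataclass(frozen=True)
class RunConfig:
    """Settings for the reproduction workflows.

    Defaults reproduce the study conditions: B-DNA material, C170L/C170N
    calibration targets, the published construct presets, the 5..65 pN
    schedule, and per-helix sweep densities of 1 junction participation and
    0.5 nicks per 21 bp.
    """

    material: MaterialParams = field(default_factory=MaterialParams)
    chamber: FlowChamber = field(default_factory=FlowChamber)
    ligated_target: str = "C170L"
    nicked_target: str = "C170N"
    predict: tuple[str, ...] = ("C85L", "C85N", "C170L", "C170N",
                                "6HB", "10HB")
    sweep_n: tuple[int, ...] = (2, 6, 9, 10, 16)
    sweep_packings: tuple[str, ...] = ("honeycomb", "square")
    sweep_junction_density: float = 1.0
    sweep_nick_density: float = 0.5
    sweep_length_nm: float = 428.0
    roundtrip_constructs: tuple[str, ...] = ("C85L", "C85N", "C170L", "C170N")
    roundtrip_n_seeds: int = 50
    qc_tolerance: float = 0.2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "material" in kwargs:
            kwargs["material"] = MaterialParams(**kwargs["material"])
        if "chamber" in kwargs:
            kwargs["chamber"] = FlowChamber(**kwargs["chamber"])
        for key in ("predict", "sweep_n", "sweep_packings",
                    "roundtrip_constructs"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(outdir: Path, config: RunConfig, what: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"workflow": what, "config_sha256": config.digest(),
                "seed": config.seed, "nanobeam_version": __version__}
    (outdir / f"{what}_manifest.json").write_text(
        json.dumps(manifest, indent=1))


def run_table1(config: RunConfig | None = None,
               outdir: str | Path | None = None
               ) -> tuple[pd.DataFrame, CalibrationResult]:
    """Calibrate alpha/beta on the 21 bp-spacing pair and predict the model
    stiffness column for all presets.

    Deterministic; repeated runs are byte-identical.
    """
    config = config or RunConfig()
    calib = calibrate_two_step(
        preset(config.ligated_target), preset(config.nicked_target),
        config.material,
        MEASURED[config.ligated_target], MEASURED[config.nicked_target])
    table = predict_constructs(calib, [preset(n) for n in config.predict])
    table["measured_mean_pN"] = [
        MEASURED[n].mean_pN if n in MEASURED else np.nan
        for n in table["construct"]]
    table["measured_sd_pN"] = [
        MEASURED[n].sd_pN if n in MEASURED and MEASURED[n].sd_pN else np.nan
        for n in table["construct"]]
    if outdir is not None:
        outdir = Path(outdir)
        _write_manifest(outdir, config, "table1")
        table.to_csv(outdir / "table1_model.csv", index=False)
        (outdir / "calibration.json").write_text(
            json.dumps(calib.to_dict(), indent=1))
    return table, calib


def run_bundle_sweep(config: RunConfig | None = None,
                     outdir: str | Path | None = None) -> pd.DataFrame:
    """Stiffness vs helix count for honeycomb and square packings, using
    calibrated degradation factors and the configured densities."""
    config = config or RunConfig()
    _, calib = run_table1(config)
    table = bundle_sweep(list(config.sweep_n), list(config.sweep_packings),
                         calib.material,
                         config.sweep_junction_density,
                         config.sweep_nick_density,
                         length_nm=config.sweep_length_nm)
    if outdir is not None:
        outdir = Path(outdir)
        _write_manifest(outdir, config, "bundle_sweep")
        table.to_csv(outdir / "bundle_sweep.csv", index=False)
    return table


def run_synthetic_roundtrip(config: RunConfig | None = None,
                            outdir: str | Path | None = None) -> dict:
    """Generate synthetic cohorts at the model stiffness of each construct,
    run QC + extraction, and report recovery statistics.

    For each construct, one good tether is simulated per seed; recovery is
    summarized by the median stiffness and median relative error.  Ordering
    preservation counts the seeds for which the recovered stiffness ranks
    the constructs exactly as their true values do.  QC sensitivity and
    specificity come from dedicated all-good / all-bad cohorts.
    """
    config = config or RunConfig()
    table, calib = run_table1(config)
    model_k = dict(zip(table["construct"], table["model_stiffness_pN"]))
    schedule = schedule_default()
    n_seeds = config.roundtrip_n_seeds

    recovered: dict[str, np.ndarray] = {}
    per_construct = []
    for idx, name in enumerate(config.roundtrip_constructs):
        k_true = model_k[name]
        L0 = preset(name).length_nm
        trajs, _ = generate_cohort(
            n_seeds, k_true, bad_fraction=0.0,
            seed=config.seed + 1000 * (idx + 1), schedule=schedule, L0=L0)
        df = summarize_cohort(trajs, qc_tolerance=config.qc_tolerance)
        recovered[name] = df["stiffness_pN"].to_numpy()
        per_construct.append({
            "construct": name, "K_true_pN": k_true,
            "median_recovered_pN": float(np.median(recovered[name])),
            "median_rel_error": float(np.median(
                np.abs(recovered[name] - k_true) / k_true)),
            "qc_pass_rate": float(df["qc_pass"].mean()),
        })

    order = sorted(config.roundtrip_constructs,
                   key=lambda n: model_k[n], reverse=True)
    ok = np.ones(n_seeds, dtype=bool)
    for a, b in zip(order, order[1:]):
        ok &= recovered[a] > recovered[b]
    ordering_rate = float(ok.mean())

    good, _ = generate_cohort(100, model_k[order[0]], bad_fraction=0.0,
                              seed=config.seed + 7919, schedule=schedule)
    bad, _ = generate_cohort(100, model_k[order[0]], bad_fraction=1.0,
                             seed=config.seed + 104729, schedule=schedule)
    qc_good = summarize_cohort(good, qc_tolerance=config.qc_tolerance)
    qc_bad = summarize_cohort(bad, qc_tolerance=config.qc_tolerance)

    report = {
        "per_construct": per_construct,
        "ordering_preserved_rate": ordering_rate,
        "qc_good_pass_rate": float(qc_good["qc_pass"].mean()),
        "qc_bad_reject_rate": float(1.0 - qc_bad["qc_pass"].mean()),
        "n_seeds": n_seeds,
        "alpha": calib.alpha, "beta": calib.beta,
    }
    if outdir is not None:
        outdir = Path(outdir)
        _write_manifest(outdir, config, "roundtrip")
        (outdir / "roundtrip_report.json").write_text(
            json.dumps(report, indent=1))
    return report
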