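"""Extraction pipeline: QC, unstretched length, slope fitting."""

import numpy as np
import pytest

from nanobeam.errors import InsufficientDataError, ValidationError
from nanobeam.extraction import (FORWARD, PRE, Trajectory, analyze_trajectory,
                                 fit_stiffness, plateaus,
                                 qc_symmetric_reversal, summarize_cohort,
                                 unstretched_length)
from nanobeam.flow import ForceSchedule, schedule_default
from nanobeam.synthetic import (TetherModel, generate_cohort, mean_extension,
                                simulate_trajectory)


def make_traj(K=181.0, noise=0.0, seed=0, **kwargs):
    m = TetherModel(K_true=K, noise_sigma=noise, **kwargs)
    return simulate_trajectory(m, schedule_default(), seed=seed)


def shift(traj, offset):
    return Trajectory(time=traj.time, displacement=traj.displacement + offset,
                      force=traj.force, phase=traj.phase)


class TestQC:
    def test_mirrored_tether_passes_with_zero_score(self):
        qc = qc_symmetric_reversal(make_traj())
        assert qc.status == "pass"
        assert qc.score == pytest.approx(0.0, abs=1e-12)

    def test_half_reversal_fails(self):
        traj = make_traj(bad_tether=True, reverse_asymmetry=0.5)
        qc = qc_symmetric_reversal(traj, tolerance=0.2)
        assert qc.status == "fail"
        assert qc.score == pytest.approx(0.5, abs=1e-9)

    def test_missing_reverse_phase_not_evaluable(self):
        sched = ForceSchedule(steps=schedule_default().steps)  # no reverse
        m = TetherModel(K_true=181.0, noise_sigma=0.0)
        traj = simulate_trajectory(m, sched, seed=0)
        assert qc_symmetric_reversal(traj).status == "not_evaluable"

    def test_noisy_good_tethers_mostly_pass(self):
        trajs, _ = generate_cohort(100, 181.0, 0.0, seed=5)
        rate = np.mean([qc_symmetric_reversal(t).passed for t in trajs])
        assert rate > 0.95


class TestUnstretchedLength:
    def test_noiseless_l0_close_to_contour_length(self):
        traj = make_traj()
        L0 = unstretched_length(traj)
        m = TetherModel(K_true=181.0, noise_sigma=0.0)
        expected = (mean_extension(m, 10.0)
                    - mean_extension(m, m.rest_force_pN))
        assert L0 == pytest.approx(expected, abs=1e-9)
        assert L0 == pytest.approx(1224.0, rel=0.05)  # straightened, ~L0

    def test_no_ten_pn_plateau_is_config_error(self):
        sched = ForceSchedule(steps=((20.0, 10.0), (30.0, 10.0),
                                     (40.0, 10.0), (50.0, 10.0)))
        traj = simulate_trajectory(TetherModel(K_true=181.0, noise_sigma=0.0),
                                   sched, seed=0)
        with pytest.raises(ValidationError):
            unstretched_length(traj)

    def test_independent_of_frames_after_plateau(self):
        full = make_traj()
        # truncate right after the 10 pN step (pre 5 s + two steps of 10 s)
        n = int(round((5 + 20) * full.frame_rate))
        cut = Trajectory(time=full.time[:n], displacement=full.displacement[:n],
                         force=full.force[:n], phase=full.phase[:n])
        assert unstretched_length(cut) == pytest.approx(
            unstretched_length(full), abs=1e-9)


class TestFitStiffness:
    def test_noiseless_linear_tether_machine_precision(self):
        # synthetic linear plateau data: F = s * x exactly
        s, L0 = 0.1479, 1224.0
        forces = np.repeat(np.arange(20.0, 70.0, 5.0), 50)
        time = np.arange(forces.size) / 5.0
        traj = Trajectory(time=time, displacement=forces / s, force=forces,
                          phase=np.full(forces.size, FORWARD, np.int8))
        res = fit_stiffness(traj, L0)
        assert res.slope == pytest.approx(s, rel=1e-12)
        assert res.apparent_stiffness == pytest.approx(s * L0, rel=1e-12)
        assert res.apparent_stiffness == pytest.approx(181.0, abs=0.1)

    def test_insufficient_plateaus(self):
        traj = make_traj()
        with pytest.raises(InsufficientDataError):
            fit_stiffness(traj, 1224.0, force_threshold=62.0)

    def test_offset_invariance(self):
        traj = make_traj(noise=20.0, seed=3)
        base = analyze_trajectory(traj)
        moved = analyze_trajectory(shift(traj, 500.0))
        assert moved["stiffness_pN"] == pytest.approx(
            base["stiffness_pN"], rel=1e-9)
        assert moved["L0_nm"] == pytest.approx(base["L0_nm"], rel=1e-9)

    def test_resampling_invariance(self):
        """Doubling the frame rate preserves plateau means and hence the
        recovered stiffness (noiseless)."""
        k5 = analyze_trajectory(make_traj())["stiffness_pN"]
        m = TetherModel(K_true=181.0, noise_sigma=0.0, frame_rate=10.0)
        traj10 = simulate_trajectory(m, schedule_default(), seed=0)
        k10 = analyze_trajectory(traj10)["stiffness_pN"]
        assert k10 == pytest.approx(k5, rel=1e-9)

    def test_wlc_cohort_recovery_within_tolerance(self):
        trajs, _ = generate_cohort(50, 200.0, 0.0, seed=11)
        df = summarize_cohort(trajs)
        median = df["stiffness_pN"].median()
        assert abs(median - 200.0) / 200.0 < 0.15


class TestTrajectoryContainer:
    def test_csv_round_trip(self, tmp_path):
        traj = make_traj(noise=20.0, seed=7)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert np.allclose(back.displacement, traj.displacement)
        assert np.array_equal(back.phase, traj.phase)

    def test_csv_with_schedule_reconstruction(self, tmp_path):
        traj = make_traj()
        path = tmp_path / "bare.csv"
        traj.to_frame()[["time_s", "displacement_nm"]].to_csv(path,
                                                              index=False)
        back = Trajectory.from_csv(path, schedule=schedule_default())
        assert np.array_equal(back.force, traj.force)

    def test_validation(self):
        with pytest.raises(ValidationError):
            Trajectory(time=np.array([0.0, 0.2, 0.5]),
                       displacement=np.zeros(3), force=np.zeros(3),
                       phase=np.zeros(3, np.int8))  # non-uniform
        with pytest.raises(ValidationError):
            Trajectory(time=np.array([0.0, 0.2]),
                       displacement=np.array([-1.0, 0.0]),
                       force=np.zeros(2), phase=np.zeros(2, np.int8))
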