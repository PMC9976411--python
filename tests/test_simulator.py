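"""End-to-end Monte-Carlo experiment simulations."""

import dataclasses

import numpy as np
import pytest

from arguide.guidance import GuidanceMethod
from arguide.registration import estimate_fle_from_fre, simulate_target_errors
from arguide.scene import build_exp2_scene
from arguide.simulator import (
    CameraModel,
    NoiseModel,
    OperatorNoise,
    calibrate_noise_from_paper,
    records_to_dataframe,
    simulate_overlay_experiment,
    simulate_placement_experiment,
    simulate_targeting_experiment,
)

ZERO = NoiseModel()
FLE_CAL = calibrate_noise_from_paper(0.81, 7)


class TestNoiseModel:
    def test_all_zero_by_default(self):
        assert ZERO.is_zero()

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(fle_sigma_mm=-0.1)
        with pytest.raises(ValueError):
            OperatorNoise(depth_mm=-1.0)

    def test_yaml_round_trip_with_every_field_explicit(self, tmp_path):
        noise = NoiseModel(
            fle_sigma_mm=0.5,
            frame_track_rot_deg=0.1,
            needle_track_trans_mm=0.2,
            operator={GuidanceMethod.FREE_HAND: OperatorNoise(1.0, 0.5, 2.0)},
        )
        path = tmp_path / "noise.yaml"
        noise.to_yaml(path)
        again = NoiseModel.from_yaml(path)
        assert again == noise
        # every scalar field appears explicitly in the file
        text = path.read_text()
        for field in (
            "fle_sigma_mm", "caliper_sigma_mm", "frame_track_rot_deg",
            "frame_track_trans_mm", "needle_track_rot_deg",
            "needle_track_trans_mm", "jitter_sigma_mm", "operator",
        ):
            assert field in text

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            NoiseModel.from_dict({"fle_sigma": 1.0})

    def test_calibration_from_reported_fre(self):
        assert calibrate_noise_from_paper(0.0, 7).is_zero()
        fle = estimate_fle_from_fre(0.81, 7)
        assert FLE_CAL.fle_sigma_mm == pytest.approx(fle / np.sqrt(3.0), rel=1e-12)
        assert FLE_CAL.fle_sigma_mm == pytest.approx(0.553, abs=5e-4)


class TestCamera:
    def test_calibration_on_the_40mm_square(self):
        """Two points 40 mm apart, fronto-parallel at working distance, read 40 mm."""
        cam = CameraModel.look_at([0.0, 0.0, -450.0], [0.0, 0.0, 0.0])
        a = cam.project([-20.0, 0.0, 0.0])
        b = cam.project([20.0, 0.0, 0.0])
        assert np.linalg.norm(a - b) == pytest.approx(40.0, abs=1e-6)

    def test_projection_shrinks_content_beyond_working_distance(self):
        cam = CameraModel.look_at([0.0, 0.0, -450.0], [0.0, 0.0, 0.0])
        a = cam.project([-20.0, 0.0, 100.0])
        b = cam.project([20.0, 0.0, 100.0])
        assert np.linalg.norm(a - b) < 40.0

    def test_point_behind_camera_rejected(self):
        cam = CameraModel.look_at([0.0, 0.0, -450.0], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            cam.project([0.0, 0.0, -500.0])


class TestProtocolCounts:
    def test_overlay_default_emits_56_records(self):
        assert len(simulate_overlay_experiment(noise=ZERO, seed=0)) == 56

    def test_overlay_count_scales_with_device_positions(self):
        assert len(simulate_overlay_experiment(noise=ZERO, n_positions=3, seed=0)) == 24
        assert len(simulate_overlay_experiment(noise=ZERO, n_positions=9, seed=0)) == 72

    def test_targeting_default_emits_24_records(self):
        assert len(simulate_targeting_experiment(noise=ZERO, seed=0)) == 24

    def test_placement_default_emits_8_insertions_per_operator(self):
        scene, plans = build_exp2_scene(seed=0)
        recs = simulate_placement_experiment(scene, plans, noise=ZERO, seed=0)
        df = records_to_dataframe(recs)
        assert len(df) == 24
        per_op = df.groupby("operator").size()
        assert (per_op == 8).all()
        per_op_method = df.groupby(["operator", "method"]).size()
        assert (per_op_method == 4).all()


class TestZeroNoisePipeline:
    def test_all_three_experiments_are_error_free(self):
        scene, plans = build_exp2_scene(seed=1)
        for recs in (
            simulate_overlay_experiment(noise=ZERO, seed=1),
            simulate_targeting_experiment(noise=ZERO, seed=1),
            simulate_placement_experiment(scene, plans, noise=ZERO, seed=1),
        ):
            assert max(r.error_mm for r in recs) < 1e-9


class TestReproducibility:
    def test_same_seed_same_errors_different_seed_different(self):
        a = simulate_overlay_experiment(noise=FLE_CAL, seed=5)
        b = simulate_overlay_experiment(noise=FLE_CAL, seed=5)
        c = simulate_overlay_experiment(noise=FLE_CAL, seed=6)
        assert [r.error_mm for r in a] == [r.error_mm for r in b]
        assert [r.error_mm for r in a] != [r.error_mm for r in c]

    def test_placement_reproducible(self):
        scene, plans = build_exp2_scene(seed=2)
        noise = dataclasses.replace(
            FLE_CAL,
            operator={m: OperatorNoise(1.0, 1.0, 3.0) for m in GuidanceMethod},
        )
        a = simulate_placement_experiment(scene, plans, noise=noise, seed=3)
        b = simulate_placement_experiment(scene, plans, noise=noise, seed=3)
        assert [r.error_mm for r in a] == [r.error_mm for r in b]


class TestErrorPropagation:
    def test_overlay_rms_monotone_in_each_sigma(self):
        """RMS overlay error is non-decreasing in every noise source."""
        grids = {
            "fle_sigma_mm": (0.0, 0.5, 1.0),
            "caliper_sigma_mm": (0.0, 0.5, 1.0),
            "frame_track_rot_deg": (0.0, 0.2, 0.4),
            "frame_track_trans_mm": (0.0, 0.5, 1.0),
        }
        for field, values in grids.items():
            rms = []
            for v in values:
                recs = simulate_overlay_experiment(
                    noise=NoiseModel(**{field: v}), n_positions=60, seed=7
                )
                rms.append(np.sqrt(np.mean([r.error_mm**2 for r in recs])))
            assert rms[0] <= rms[1] <= rms[2], field
            assert rms[2] > rms[0], field

    def test_overlay_projection_never_increases_distance(self, frame, bead_positions_world):
        """2-D overlay RMS (registration noise only) <= 3-D TRE RMS at the beads."""
        fle = estimate_fle_from_fre(0.81, 7)
        recs = simulate_overlay_experiment(noise=FLE_CAL, n_positions=250, seed=8)
        rms_2d = np.sqrt(np.mean([r.error_mm**2 for r in recs]))
        errs = simulate_target_errors(
            frame.fiducials, fle, bead_positions_world, 2000, seed=8
        )
        rms_3d = np.sqrt(np.mean(errs**2))
        assert rms_2d <= rms_3d

    def test_targeting_variances_from_independent_chains_add(self):
        """Frame-chain and needle-chain noise contribute independent variance."""
        frame_only = NoiseModel(fle_sigma_mm=0.5, frame_track_trans_mm=0.3)
        needle_only = NoiseModel(needle_track_rot_deg=0.2, needle_track_trans_mm=0.4)
        both = NoiseModel(
            fle_sigma_mm=0.5, frame_track_trans_mm=0.3,
            needle_track_rot_deg=0.2, needle_track_trans_mm=0.4,
        )

        def mean_sq(noise, seed):
            recs = simulate_targeting_experiment(noise=noise, n_poses=400, seed=seed)
            return np.mean([r.error_mm**2 for r in recs])

        v_frame = mean_sq(frame_only, 20)
        v_needle = mean_sq(needle_only, 21)
        v_both = mean_sq(both, 22)
        assert v_both == pytest.approx(v_frame + v_needle, rel=0.10)

    def test_placement_error_exceeds_pure_system_error(self):
        """Operator noise adds variance on top of the system (tracking) error."""
        scene, plans = build_exp2_scene(seed=4)
        with_op = dataclasses.replace(
            FLE_CAL,
            operator={m: OperatorNoise(1.0, 1.0, 3.0) for m in GuidanceMethod},
        )
        sys_only = FLE_CAL

        def rms(noise, n_ops=12):
            recs = simulate_placement_experiment(
                scene, plans, noise=noise, n_operators=n_ops, seed=9
            )
            return np.sqrt(np.mean([r.error_mm**2 for r in recs]))

        assert rms(with_op) > rms(sys_only)
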