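"""Guidance display logic and simulated insertions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from arguide.geometry import CoordinateSpace, RigidTransform, compose, rotation_about_axis
from arguide.guidance import (
    AlignmentState,
    GuidanceConfig,
    ProximityState,
    free_hand_update,
    insertion_trajectory,
    planned_path_score,
    states_to_csv_rows,
)
from arguide.scene import InsertionPlan, NeedleModel
from arguide.simulator import FreeHandOperator, OperatorNoise, PlannedPathOperator

NEEDLE = NeedleModel()
CFG = GuidanceConfig()
NF = CoordinateSpace.NEEDLE_FRAME
WORLD = CoordinateSpace.WORLD


def _pose_with_tip(tip, axis):
    """World pose placing the needle tip at ``tip`` pointing along ``axis``."""
    from arguide.simulator import _pose_for_tip

    return _pose_for_tip(NEEDLE, np.asarray(tip, float), np.asarray(axis, float))


class TestFreeHandUpdate:
    def test_tip_on_target(self):
        s = free_hand_update([10.0, 20.0, 30.0], _pose_with_tip([10, 20, 30], [0, 0, 1]), NEEDLE)
        assert s.tip_target_distance_mm == pytest.approx(0.0, abs=1e-9)
        assert s.proximity_state is ProximityState.HIT
        assert s.predicted_miss_mm == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "dist,expected",
        [
            (0.9, ProximityState.HIT),
            (4.9, ProximityState.NEAR),
            (5.0, ProximityState.NEAR),  # the 5-mm vicinity ring is inclusive
            (5.1, ProximityState.FAR),
        ],
    )
    def test_proximity_thresholds(self, dist, expected):
        pose = _pose_with_tip([0, 0, 0], [0, 0, 1])
        s = free_hand_update([dist, 0.0, 0.0], pose, NEEDLE)
        assert s.proximity_state is expected

    def test_proximity_is_monotone_in_distance(self):
        order = {ProximityState.HIT: 0, ProximityState.NEAR: 1, ProximityState.FAR: 2}
        pose = _pose_with_tip([0, 0, 0], [1, 0, 0])
        states = [
            free_hand_update([d, 0.0, 0.0], pose, NEEDLE).proximity_state
            for d in np.linspace(0.1, 10.0, 50)
        ]
        ranks = [order[s] for s in states]
        assert ranks == sorted(ranks)

    def test_aimed_exactly_at_target(self):
        pose = _pose_with_tip([0, 0, 0], [0, 0, 1])
        s = free_hand_update([0.0, 0.0, 50.0], pose, NEEDLE)
        assert s.angular_deviation_deg == pytest.approx(0.0, abs=1e-9)
        assert s.alignment_state is AlignmentState.ALIGNED
        assert s.predicted_miss_mm == pytest.approx(0.0, abs=1e-9)
        assert s.depth_remaining_mm == pytest.approx(50.0)

    def test_target_behind_tip_miss_equals_distance(self):
        pose = _pose_with_tip([0, 0, 0], [0, 0, 1])
        s = free_hand_update([0.0, 0.0, -30.0], pose, NEEDLE)
        assert s.predicted_miss_mm == pytest.approx(s.tip_target_distance_mm)

    def test_predicted_miss_never_exceeds_distance(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            pose = _pose_with_tip(rng.uniform(-50, 50, 3), rng.normal(size=3))
            s = free_hand_update(rng.uniform(-50, 50, 3), pose, NEEDLE)
            assert s.predicted_miss_mm <= s.tip_target_distance_mm + 1e-9

    def test_world_frame_independence(self):
        """A common rigid transform of target and pose leaves the state unchanged."""
        rng = np.random.default_rng(13)
        pose = _pose_with_tip([5.0, -10.0, 20.0], [0.3, 0.2, 1.0])
        target = np.array([10.0, 0.0, 60.0])
        s0 = free_hand_update(target, pose, NEEDLE)
        common = RigidTransform(
            Rotation.from_rotvec(rng.uniform(-2, 2, 3)).as_matrix(),
            rng.uniform(-100, 100, 3), WORLD, WORLD,
        )
        s1 = free_hand_update(common.apply(target), compose(pose, common), NEEDLE)
        assert s1.tip_target_distance_mm == pytest.approx(s0.tip_target_distance_mm, abs=1e-9)
        assert s1.angular_deviation_deg == pytest.approx(s0.angular_deviation_deg, abs=1e-7)
        assert s1.predicted_miss_mm == pytest.approx(s0.predicted_miss_mm, abs=1e-9)
        assert s1.proximity_state is s0.proximity_state


class TestPlannedPathScore:
    PLAN = InsertionPlan("p", [0.0, 0.0, 80.0], [0.0, 0.0, 0.0])

    def test_on_plan_at_target_scores_zero(self):
        lateral, angle, depth = planned_path_score(
            self.PLAN, _pose_with_tip([0, 0, 80.0], [0, 0, 1]), NEEDLE
        )
        assert lateral == pytest.approx(0.0, abs=1e-9)
        assert angle == pytest.approx(0.0, abs=1e-9)
        assert depth == pytest.approx(0.0, abs=1e-9)

    def test_parallel_lateral_shift(self):
        lateral, angle, _ = planned_path_score(
            self.PLAN, _pose_with_tip([2.0, 0, 40.0], [0, 0, 1]), NEEDLE
        )
        assert lateral == pytest.approx(2.0, abs=1e-9)
        assert angle == pytest.approx(0.0, abs=1e-9)

    def test_overshoot_past_the_length_marker(self):
        _, _, depth = planned_path_score(
            self.PLAN, _pose_with_tip([0, 0, 83.0], [0, 0, 1]), NEEDLE
        )
        assert depth == pytest.approx(3.0, abs=1e-9)

    def test_angled_needle(self):
        axis = np.array([np.sin(np.deg2rad(10)), 0.0, np.cos(np.deg2rad(10))])
        _, angle, _ = planned_path_score(
            self.PLAN, _pose_with_tip([0, 0, 40.0], axis), NEEDLE
        )
        assert angle == pytest.approx(10.0, abs=1e-9)


class TestInsertionTrajectory:
    PLAN = InsertionPlan("p", [10.0, 20.0, 80.0], [5.0, 18.0, 0.0])

    def test_perfect_operator_hits_with_either_method(self):
        for ctor in (
            lambda rng: PlannedPathOperator(self.PLAN, NEEDLE, OperatorNoise(), rng),
            lambda rng: FreeHandOperator(
                self.PLAN.target, self.PLAN.entry, NEEDLE, OperatorNoise(), rng
            ),
        ):
            states = insertion_trajectory(
                ctor(np.random.default_rng(0)), self.PLAN.target, NEEDLE, CFG
            )
            assert states[-1].tip_target_distance_mm < CFG.hit_threshold_mm

    def test_same_seed_gives_identical_trajectory(self):
        noise = OperatorNoise(2.0, 1.0, 2.0)

        def run():
            op = PlannedPathOperator(self.PLAN, NEEDLE, noise, np.random.default_rng(7))
            return insertion_trajectory(op, self.PLAN.target, NEEDLE, CFG)

        a, b = run(), run()
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.tip_position, sb.tip_position)

    def test_depth_noise_increases_mean_depth_error(self):
        """Mean |stopping-depth error| grows strictly with operator depth sigma."""
        means = []
        for sigma in (0.5, 1.5, 3.0):
            errs = []
            for s in range(200):
                op = PlannedPathOperator(
                    self.PLAN, NEEDLE, OperatorNoise(0.0, 0.0, sigma),
                    np.random.default_rng(s),
                )
                states = insertion_trajectory(op, self.PLAN.target, NEEDLE, CFG)
                _, _, depth_err = planned_path_score(
                    self.PLAN, op._pose(), NEEDLE
                )
                errs.append(abs(depth_err))
            means.append(np.mean(errs))
        assert means[0] < means[1] < means[2]

    def test_state_stream_serializes(self):
        op = PlannedPathOperator(self.PLAN, NEEDLE, OperatorNoise(), np.random.default_rng(0))
        states = insertion_trajectory(op, self.PLAN.target, NEEDLE, CFG)
        df = states_to_csv_rows(states)
        assert list(df.columns) == [
            "tick", "tip_x", "tip_y", "tip_z", "dist_mm", "angle_deg",
            "miss_mm", "depth_rem_mm", "prox_state", "align_state",
        ]
        assert len(df) == len(states)


def test_guidance_config_validation():
    with pytest.raises(ValueError):
        GuidanceConfig(hit_threshold_mm=6.0)  # hit must sit inside the ring
    with pytest.raises(ValueError):
        GuidanceConfig(alignment_threshold_deg=0.0)
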