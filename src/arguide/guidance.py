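"""Deterministic guidance logic for the two needle-guidance methods.

Free-hand guidance shows the target plus the live tracked needle and gives
the operator three cues: a forward extension of the needle line, a shaft
state for the approach angle, and a target state for tip proximity (the
target changes appearance within 5 mm of the tip).  Planned-path guidance
shows a pre-planned trajectory (entry, path, target, depth marker) that the
operator aligns the untracked needle to.

Everything here is a pure function of poses and configuration: tracking
noise, operator behaviour and timing live in the simulator, not here.
Proximity is measured tip to target *center* (the experimental targets are
beads).  "Depth remaining" in free-hand mode is the along-axis distance from
the tip to the point of closest approach to the target, since free-hand mode
has no planned depth and the stop decision is the operator's.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .geometry import RigidTransform
from .scene import InsertionPlan, NeedleModel

__all__ = [
    "GuidanceConfig",
    "GuidanceState",
    "ProximityState",
    "AlignmentState",
    "GuidanceMethod",
    "ConvergenceError",
    "free_hand_update",
    "planned_path_score",
    "insertion_trajectory",
    "states_to_csv_rows",
]


class ProximityState(str, Enum):
    FAR = "FAR"
    NEAR = "NEAR"  # within the 5-mm vicinity ring
    HIT = "HIT"


class AlignmentState(str, Enum):
    ALIGNED = "ALIGNED"
    OFF_AXIS = "OFF_AXIS"


class GuidanceMethod(str, Enum):
    PLANNED_PATH = "PLANNED_PATH"
    FREE_HAND = "FREE_HAND"


class ConvergenceError(RuntimeError):
    """Simulated insertion failed to stop within the step budget."""


@dataclass(frozen=True)
class GuidanceConfig:
    """Display-state thresholds.

    The 5-mm proximity ring is the one threshold the display defines; the
    hit threshold (stop criterion for simulated operators) and the shaft
    alignment threshold are configurable design choices.
    """

    proximity_threshold_mm: float = 5.0
    hit_threshold_mm: float = 1.0
    alignment_threshold_deg: float = 3.0
    depth_tolerance_mm: float = 1.0
    extension_length_mm: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.hit_threshold_mm < self.proximity_threshold_mm):
            raise ValueError("require 0 < hit threshold < proximity threshold")
        if self.alignment_threshold_deg <= 0:
            raise ValueError("alignment threshold must be positive")


@dataclass(frozen=True)
class GuidanceState:
    """Per-tick guidance feedback for a posed needle and a target."""

    tip_position: np.ndarray  # mm, WORLD
    tip_target_distance_mm: float
    angular_deviation_deg: float  # needle axis vs tip->target direction
    predicted_miss_mm: float  # closest approach of the forward needle ray
    depth_remaining_mm: float
    proximity_state: ProximityState
    alignment_state: AlignmentState


def free_hand_update(
    target: np.ndarray,
    needle_pose: RigidTransform,
    needle: NeedleModel,
    config: GuidanceConfig = GuidanceConfig(),
) -> GuidanceState:
    """Compute the free-hand feedback state for one needle pose.

    ``target`` is in the pose's destination (WORLD) space.  Pure function.
    """
    target = np.asarray(target, dtype=float).reshape(3)
    tip = needle_pose.apply(needle.tip_offset_mm)
    axis = needle_pose.rotation @ needle.axis_direction
    to_target = target - tip
    dist = float(np.linalg.norm(to_target))

    if dist < 1e-12:
        angle = 0.0
        miss = 0.0
        along = 0.0
    else:
        along = float(to_target @ axis)
        cosang = np.clip(along / dist, -1.0, 1.0)
        angle = float(np.rad2deg(np.arccos(cosang)))
        if along <= 0.0:
            # target behind the tip: the forward ray's closest point is the tip
            miss = dist
        else:
            miss = float(np.linalg.norm(to_target - along * axis))

    if dist <= config.hit_threshold_mm:
        prox = ProximityState.HIT
    elif dist <= config.proximity_threshold_mm:
        prox = ProximityState.NEAR
    else:
        prox = ProximityState.FAR
    align = (
        AlignmentState.ALIGNED
        if angle <= config.alignment_threshold_deg
        else AlignmentState.OFF_AXIS
    )
    return GuidanceState(
        tip_position=tip,
        tip_target_distance_mm=dist,
        angular_deviation_deg=angle,
        predicted_miss_mm=miss,
        depth_remaining_mm=max(along, 0.0),
        proximity_state=prox,
        alignment_state=align,
    )


def planned_path_score(
    plan: InsertionPlan,
    needle_pose: RigidTransform,
    needle: NeedleModel,
) -> tuple[float, float, float]:
    """Deviation of a posed needle from the planned trajectory.

    Returns ``(lateral_offset_mm, axis_angle_deg, depth_error_mm)``:
    the common-perpendicular distance between the needle axis line and the
    planned path (plan parameter clamped to the planned segment), the angle
    between the two directions, and the inserted depth along the plan minus
    the planned depth (positive = advanced past the planned length marker).
    """
    tip = needle_pose.apply(needle.tip_offset_mm)
    axis = needle_pose.rotation @ needle.axis_direction
    u = plan.direction
    axis_angle = float(np.rad2deg(np.arccos(np.clip(axis @ u, -1.0, 1.0))))

    # closest approach between plan line (entry + s*u) and axis line (tip + t*axis)
    w = plan.entry - tip
    a_dot_u = float(axis @ u)
    denom = 1.0 - a_dot_u**2
    if denom < 1e-12:  # parallel: perpendicular point-to-line distance
        lateral = float(np.linalg.norm(w - (w @ axis) * axis))
    else:
        s = float(((w @ axis) * a_dot_u - (w @ u)) / denom)
        s = float(np.clip(s, 0.0, plan.planned_depth_mm))
        p_on_plan = plan.entry + s * u
        v = p_on_plan - tip
        lateral = float(np.linalg.norm(v - (v @ axis) * axis))

    depth_error = float((tip - plan.entry) @ u - plan.planned_depth_mm)
    return lateral, axis_angle, depth_error


def insertion_trajectory(
    controller,
    target: np.ndarray,
    needle: NeedleModel,
    config: GuidanceConfig = GuidanceConfig(),
    max_steps: int = 1000,
) -> list[GuidanceState]:
    """Run a simulated insertion until the controller stops.

    ``controller`` is an operator policy with ``start() -> RigidTransform``
    and ``step(state) -> (RigidTransform, done)`` (see the simulator module
    for the two built-in operator models).  The returned list of states is
    deterministic given the controller's internal seed; the final state is
    the placement outcome.
    """
    states: list[GuidanceState] = []
    pose = controller.start()
    for _ in range(max_steps):
        state = free_hand_update(target, pose, needle, config)
        states.append(state)
        pose, done = controller.step(state)
        if done:
            states.append(free_hand_update(target, pose, needle, config))
            return states
    raise ConvergenceError(f"insertion did not stop within {max_steps} steps")


def states_to_csv_rows(states: list[GuidanceState]) -> "pd.DataFrame":
    """Guidance-state stream as one CSV row per tick."""
    import pandas as pd

    return pd.DataFrame(
        {
            "tick": np.arange(len(states)),
            "tip_x": [s.tip_position[0] for s in states],
            "tip_y": [s.tip_position[1] for s in states],
            "tip_z": [s.tip_position[2] for s in states],
            "dist_mm": [s.tip_target_distance_mm for s in states],
            "angle_deg": [s.angular_deviation_deg for s in states],
            "miss_mm": [s.predicted_miss_mm for s in states],
            "depth_rem_mm": [s.depth_remaining_mm for s in states],
            "prox_state": [s.proximity_state.value for s in states],
            "align_state": [s.alignment_state.value for s in states],
        }
    )
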