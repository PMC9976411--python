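"""Physical models and fixture generators for the phantom experiments.

Coordinate convention for PATIENT_FRAME (the fiducial-bearing reference frame
clamped against the perineum / phantom surface): origin at the center of the
working-window base edge, x lateral (+right), y up along the lower plate,
z into the phantom (depth).  The lower plate therefore lies in the z = 0
plane and "distance from the frame base" is simply z.

The frame's upper plate (90 x 80 mm, carrying the seven 6-mm fiducials) is
hinged to the top edge of the working window and tilted 60 degrees away from
the phantom, so fiducial points are coplanar on that tilted plane.  The exact
marker layout is not prescribed by the hardware; the default here is a
deliberately asymmetric seven-point pattern (all pairwise distances distinct)
so registration has no symmetric ambiguity.  It is overridable via config.

The pelvic scene is a synthetic stand-in for an anthropomorphic pelvis
phantom: target positions are plausible inventions, not measured data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CoordinateSpace, RigidTransform, rotation_about_axis
from .registration import FiducialSet

__all__ = [
    "PatientFrameModel",
    "NeedleModel",
    "InsertionPlan",
    "PhantomScene",
    "build_patient_frame",
    "build_exp1_plate",
    "build_exp2_scene",
    "build_pelvic_scene",
    "default_frame_pose",
    "plans_to_csv",
    "plans_from_csv",
    "DEFAULT_FIDUCIAL_LAYOUT",
]

# (u, v) on the tilted upper plate: u lateral in [-45, 45], v up-plate in
# [0, 80] from the hinge.  Asymmetric: all 21 pairwise distances distinct.
DEFAULT_FIDUCIAL_LAYOUT: tuple[tuple[float, float], ...] = (
    (-40.0, 6.0),
    (36.0, 4.0),
    (-12.0, 18.0),
    (41.0, 40.0),
    (-33.0, 52.0),
    (3.0, 34.0),
    (27.0, 74.0),
)

WORKING_WINDOW_MM = (95.0, 70.0)  # width x height of the access window
UPPER_PLATE_MM = (90.0, 80.0)  # width x up-plate extent of the marker plate
PLATE_ANGLE_DEG = 60.0  # dihedral angle between upper and lower plates


@dataclass(frozen=True)
class PatientFrameModel:
    """The fiducial-bearing patient reference frame."""

    fiducials: FiducialSet  # PATIENT_FRAME coordinates, on the tilted plate
    working_window: tuple[float, float] = WORKING_WINDOW_MM
    upper_plate: tuple[float, float] = UPPER_PLATE_MM
    plate_angle_deg: float = PLATE_ANGLE_DEG
    fiducial_diameter_mm: float = 6.0

    def __post_init__(self) -> None:
        if len(self.fiducials) != 7:
            raise ValueError("patient frame carries exactly 7 fiducials")
        if self.fiducials.space is not CoordinateSpace.PATIENT_FRAME:
            raise ValueError("frame fiducials must be in PATIENT_FRAME space")
        # coplanarity with the tilted plate
        n = self.upper_plate_normal
        rel = self.fiducials.points - self.hinge_origin
        if np.max(np.abs(rel @ n)) > 1e-6:
            raise ValueError("fiducials are not coplanar with the upper plate")

    @property
    def hinge_origin(self) -> np.ndarray:
        """Center of the hinge edge shared by window and upper plate."""
        return np.array([0.0, self.working_window[1], 0.0])

    @property
    def plate_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """(u_hat, v_hat): lateral and up-plate unit vectors of the plate."""
        a = np.deg2rad(self.plate_angle_deg)
        return (
            np.array([1.0, 0.0, 0.0]),
            np.array([0.0, np.cos(a), -np.sin(a)]),
        )

    @property
    def upper_plate_normal(self) -> np.ndarray:
        a = np.deg2rad(self.plate_angle_deg)
        return np.array([0.0, np.sin(a), np.cos(a)])

    @property
    def window_center(self) -> np.ndarray:
        return np.array([0.0, self.working_window[1] / 2.0, 0.0])

    def plate_to_frame(self, uv: np.ndarray) -> np.ndarray:
        """Map (u, v) plate coordinates to 3-D PATIENT_FRAME points."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        u_hat, v_hat = self.plate_axes
        return self.hinge_origin + uv[:, :1] * u_hat + uv[:, 1:] * v_hat


def build_patient_frame(config: dict | None = None) -> PatientFrameModel:
    """Construct the reference frame, optionally with a custom marker layout.

    ``config`` keys: ``layout`` (7 [u, v] pairs on the upper plate, mm),
    ``plate_angle_deg``.  Markers outside the plate bounds are rejected.
    """
    config = dict(config or {})
    layout = np.asarray(config.pop("layout", DEFAULT_FIDUCIAL_LAYOUT), dtype=float)
    angle = float(config.pop("plate_angle_deg", PLATE_ANGLE_DEG))
    if config:
        raise ValueError(f"unknown frame config keys: {sorted(config)}")
    if layout.shape != (7, 2):
        raise ValueError("layout must provide 7 (u, v) pairs")
    half_w = UPPER_PLATE_MM[0] / 2.0
    if np.any(np.abs(layout[:, 0]) > half_w) or np.any(
        (layout[:, 1] < 0) | (layout[:, 1] > UPPER_PLATE_MM[1])
    ):
        raise ValueError("fiducial layout exceeds the upper plate bounds")
    # build via a throwaway frame to reuse the plate mapping
    proto = PatientFrameModel.__new__(PatientFrameModel)
    object.__setattr__(proto, "working_window", WORKING_WINDOW_MM)
    object.__setattr__(proto, "upper_plate", UPPER_PLATE_MM)
    object.__setattr__(proto, "plate_angle_deg", angle)
    pts = proto.plate_to_frame(layout)
    fids = FiducialSet(
        tuple(f"F{i + 1}" for i in range(7)), pts, CoordinateSpace.PATIENT_FRAME
    )
    return PatientFrameModel(fids, plate_angle_deg=angle)


@dataclass(frozen=True)
class NeedleModel:
    """Placement needle with its tracked reference plate.

    NEEDLE_FRAME has its origin at the center of the 50 x 50 mm tracking
    plate, plate in the x-y plane (normal +z).  The needle shaft makes a
    45-degree angle with the plate, i.e. 45 degrees with the plate normal.
    """

    needle_length_mm: float = 200.0  # 20-cm placement needle
    axis_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, np.sqrt(0.5), np.sqrt(0.5)])
    )
    tip_offset_mm: np.ndarray | None = None  # NEEDLE_FRAME origin -> tip
    plate_size_mm: tuple[float, float] = (50.0, 50.0)
    plate_angle_deg: float = 45.0
    length_marker_offset_mm: float = 100.0  # marker distance from the tip

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis_direction, dtype=float).reshape(3)
        ax = ax / np.linalg.norm(ax)
        object.__setattr__(self, "axis_direction", ax)
        tip = self.tip_offset_mm
        if tip is None:
            tip = self.needle_length_mm * ax
        object.__setattr__(
            self, "tip_offset_mm", np.asarray(tip, dtype=float).reshape(3)
        )
        if not (0 < self.length_marker_offset_mm <= self.needle_length_mm):
            raise ValueError("length marker must lie on the shaft")
        # plate normal is +z by construction; shaft-plate angle must agree
        axis_normal_deg = np.rad2deg(np.arccos(np.clip(abs(ax[2]), -1, 1)))
        if abs((90.0 - axis_normal_deg) - self.plate_angle_deg) > 1e-6:
            raise ValueError(
                "axis_direction inconsistent with the plate-needle angle"
            )


@dataclass(frozen=True)
class InsertionPlan:
    """Planned trajectory: entry point, target and insertion depth (IMAGE space)."""

    plan_id: str
    target: np.ndarray  # mm
    entry: np.ndarray  # mm
    planned_depth_mm: float | None = None

    def __post_init__(self) -> None:
        tgt = np.asarray(self.target, dtype=float).reshape(3)
        ent = np.asarray(self.entry, dtype=float).reshape(3)
        object.__setattr__(self, "target", tgt)
        object.__setattr__(self, "entry", ent)
        depth = self.planned_depth_mm
        if depth is None:
            depth = float(np.linalg.norm(tgt - ent))
        if depth <= 0:
            raise ValueError("planned depth must be positive")
        object.__setattr__(self, "planned_depth_mm", float(depth))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector along the planned path, entry -> target."""
        d = self.target - self.entry
        return d / np.linalg.norm(d)

    def transformed(self, t: RigidTransform) -> "InsertionPlan":
        return InsertionPlan(
            self.plan_id, t.apply(self.target), t.apply(self.entry),
            self.planned_depth_mm,
        )


def plans_to_csv(plans: list[InsertionPlan], path: str | Path) -> None:
    rows = [
        {
            "plan_id": p.plan_id,
            "tx": p.target[0], "ty": p.target[1], "tz": p.target[2],
            "ex": p.entry[0], "ey": p.entry[1], "ez": p.entry[2],
            "depth_mm": p.planned_depth_mm,
        }
        for p in plans
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def plans_from_csv(path: str | Path) -> list[InsertionPlan]:
    df = pd.read_csv(path)
    return [
        InsertionPlan(
            str(r.plan_id),
            np.array([r.tx, r.ty, r.tz]),
            np.array([r.ex, r.ey, r.ez]),
            float(r.depth_mm),
        )
        for r in df.itertuples()
    ]


def default_frame_pose() -> RigidTransform:
    """Fixed non-trivial PATIENT_FRAME -> IMAGE pose used by the fixtures.

    A real scanner places the frame at an arbitrary pose inside the volume;
    a deliberately non-identity pose keeps the registration problem honest.
    """
    rot = rotation_about_axis((0.2, 1.0, 0.3), 25.0)
    return RigidTransform(
        rot, np.array([120.0, 80.0, 40.0]),
        CoordinateSpace.PATIENT_FRAME, CoordinateSpace.IMAGE,
    )


@dataclass(frozen=True)
class PhantomScene:
    """Targets (IMAGE space) plus the pose of the reference frame."""

    name: str
    targets: FiducialSet
    frame_pose: RigidTransform  # PATIENT_FRAME -> IMAGE
    description: str = ""
    lesion_radii_mm: dict[str, float] = field(default_factory=dict)
    max_depth_mm: float = 120.0

    def __post_init__(self) -> None:
        if self.targets.space is not CoordinateSpace.IMAGE:
            raise ValueError("scene targets must be in IMAGE space")
        depths = self.targets_in_frame().points[:, 2]
        if np.any(depths < -1e-6) or np.any(depths > self.max_depth_mm + 1e-6):
            raise ValueError(
                "target(s) beyond reach of the working window "
                f"(depths {depths} mm, max {self.max_depth_mm})"
            )

    def targets_in_frame(self) -> FiducialSet:
        """Targets expressed in PATIENT_FRAME coordinates."""
        return self.targets.transformed(self.frame_pose.inverse())

    # -- JSON interface ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "description": self.description,
            "frame_pose": self.frame_pose.to_dict(),
            "targets": [
                {
                    "label": lab,
                    "x_mm": float(p[0]),
                    "y_mm": float(p[1]),
                    "z_mm": float(p[2]),
                    "space": self.targets.space.value,
                }
                for lab, p in zip(self.targets.labels, self.targets.points)
            ],
            "max_depth_mm": self.max_depth_mm,
        }
        if self.lesion_radii_mm:
            d["lesion_radii_mm"] = dict(self.lesion_radii_mm)
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomScene":
        rows = d["targets"]
        targets = FiducialSet(
            tuple(r["label"] for r in rows),
            np.array([[r["x_mm"], r["y_mm"], r["z_mm"]] for r in rows]),
            CoordinateSpace(rows[0]["space"]),
        )
        return cls(
            d["name"],
            targets,
            RigidTransform.from_dict(d["frame_pose"]),
            d.get("description", ""),
            d.get("lesion_radii_mm", {}),
            d.get("max_depth_mm", 120.0),
        )

    @classmethod
    def from_json(cls, s: str | Path) -> "PhantomScene":
        p = Path(s) if not str(s).lstrip().startswith("{") else None
        text = p.read_text() if p is not None else str(s)
        return cls.from_dict(json.loads(text))


def build_exp1_plate(
    distance_from_base_mm: float,
    frame: PatientFrameModel | None = None,
    frame_pose: RigidTransform | None = None,
) -> PhantomScene:
    """Bead plate for the overlay/targeting accuracy experiment.

    Four 1-mm beads at the corners of a 40 x 40 mm square, centered on the
    working window, at ``distance_from_base_mm`` depth (50 and 100 mm in the
    protocol).
    """
    if distance_from_base_mm < 0:
        raise ValueError("distance from base must be non-negative")
    frame = frame or build_patient_frame()
    frame_pose = frame_pose or default_frame_pose()
    c = frame.window_center
    half = 20.0
    corners = np.array(
        [
            c + [-half, -half, distance_from_base_mm],
            c + [half, -half, distance_from_base_mm],
            c + [half, half, distance_from_base_mm],
            c + [-half, half, distance_from_base_mm],
        ]
    )
    d = int(round(distance_from_base_mm))
    targets = FiducialSet(
        tuple(f"B{d}_{i + 1}" for i in range(4)),
        frame_pose.apply(corners),
        CoordinateSpace.IMAGE,
    )
    return PhantomScene(
        name=f"exp1_plate_{d}mm",
        targets=targets,
        frame_pose=frame_pose,
        description=(
            "4-bead 40x40 mm test plate centered on the working window, "
            f"{distance_from_base_mm} mm from the frame base"
        ),
    )


def build_exp2_scene(
    seed: int | np.random.Generator | None = 0,
    frame_pose: RigidTransform | None = None,
    depth_mean_mm: float = 79.6,
    depth_sd_mm: float = 3.1,
    angle_mean_deg: float = 12.8,
    angle_sd_deg: float = 6.8,
) -> tuple[PhantomScene, list[InsertionPlan]]:
    """Gel-phantom placement scene: 4 beads in a D=100 x L=120 mm cylinder.

    Entry points are drawn (seeded) on the phantom surface so plan depths and
    approach angles from the surface normal match the protocol statistics
    (depth 79.6 +/- 3.1 mm, angle 12.8 +/- 6.8 deg); bead depths land in the
    60-80 mm band.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame_pose = frame_pose or default_frame_pose()
    axis_center = np.array([0.0, 35.0, 0.0])  # cylinder axis through window center
    radius, length = 50.0, 120.0

    targets_pf, entries_pf, depths = [], [], []
    while len(targets_pf) < 4:
        depth = rng.normal(depth_mean_mm, depth_sd_mm)
        ang = np.deg2rad(rng.normal(angle_mean_deg, angle_sd_deg))
        if not (70.0 <= depth <= 90.0) or not (0.0 <= np.rad2deg(ang) <= 28.0):
            continue
        z = depth * np.cos(ang)
        if not (60.0 <= z <= 80.0):
            continue
        r = 25.0 * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        tgt = axis_center + np.array([r * np.cos(phi), r * np.sin(phi), z])
        az = rng.uniform(0, 2 * np.pi)
        direction = np.array(
            [np.sin(ang) * np.cos(az), np.sin(ang) * np.sin(az), np.cos(ang)]
        )
        entry = tgt - depth * direction  # lands exactly on the z=0 surface
        if np.linalg.norm(entry[:2] - axis_center[:2]) > radius - 2.0:
            continue
        targets_pf.append(tgt)
        entries_pf.append(entry)
        depths.append(depth)

    targets = FiducialSet(
        tuple(f"T{i + 1}" for i in range(4)),
        frame_pose.apply(np.array(targets_pf)),
        CoordinateSpace.IMAGE,
    )
    scene = PhantomScene(
        name="exp2_gel_phantom",
        targets=targets,
        frame_pose=frame_pose,
        description=(
            f"4 beads in a D={2 * radius:.0f} x L={length:.0f} mm gel cylinder; "
            "entries drawn to match the protocol depth/angle statistics"
        ),
    )
    plans = [
        InsertionPlan(
            f"P{i + 1}",
            frame_pose.apply(t),
            frame_pose.apply(e),
        )
        for i, (t, e) in enumerate(zip(targets_pf, entries_pf))
    ]
    return scene, plans


def build_pelvic_scene(frame_pose: RigidTransform | None = None) -> PhantomScene:
    """Synthetic pelvic guidance fixture (invented positions, not measured).

    Five targets behind the working window: two seminal-vesicle surrogates
    and three pseudolesion centroids with 0.5-0.7 cm^3 spherical extents.
    """
    frame_pose = frame_pose or default_frame_pose()
    labels = ("SV_LEFT", "SV_RIGHT", "LESION_A", "LESION_B", "LESION_C")
    pts_pf = np.array(
        [
            [-15.0, 45.0, 60.0],
            [15.0, 47.0, 62.0],
            [-8.0, 30.0, 72.0],
            [10.0, 28.0, 78.0],
            [0.0, 40.0, 85.0],
        ]
    )
    volumes_cm3 = {"LESION_A": 0.5, "LESION_B": 0.6, "LESION_C": 0.7}
    radii = {
        lab: float((3.0 * v * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))
        for lab, v in volumes_cm3.items()
    }
    targets = FiducialSet(labels, frame_pose.apply(pts_pf), CoordinateSpace.IMAGE)
    return PhantomScene(
        name="pelvic_fixture",
        targets=targets,
        frame_pose=frame_pose,
        description=(
            "synthetic pelvic fixture: 2 seminal-vesicle surrogates and 3 "
            "pseudolesion centroids (0.5-0.7 cm^3) at plausible depths"
        ),
        lesion_radii_mm=radii,
    )
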