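"""Rigid-body transforms between named coordinate spaces.

Every pose in the guidance chain — image volume to patient reference frame,
frame to headset, needle plate to headset — is a proper rigid transform
(rotation + translation, no scaling).  A transform maps the coordinates of a
point FROM its source space TO its destination space, so chained mappings
read left-to-right: ``compose(T_image_to_frame, T_frame_to_world)`` maps
image coordinates into world (headset) coordinates.

All lengths are millimetres; rotations are stored as 3x3 matrices and
validated to be orthonormal with determinant +1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np

__all__ = [
    "CoordinateSpace",
    "RigidTransform",
    "TransformChain",
    "SpaceMismatchError",
    "compose",
    "invert",
    "apply",
    "rotation_about_axis",
]

#: numerical tolerance for orthonormality / determinant checks
ORTHO_TOL = 1e-9


class CoordinateSpace(str, Enum):
    """Closed enumeration of the coordinate spaces in the guidance chain."""

    IMAGE = "IMAGE"  # preprocedural MRI/CT volume
    PATIENT_FRAME = "PATIENT_FRAME"  # fiducial-bearing patient reference frame
    NEEDLE_FRAME = "NEEDLE_FRAME"  # tracked plate attached to the needle
    WORLD = "WORLD"  # headset world space
    CAMERA = "CAMERA"  # recording camera at the ocular position
    SNAPSHOT_2D = "SNAPSHOT_2D"  # calibrated 2-D snapshot plane


class SpaceMismatchError(ValueError):
    """Raised when two transforms do not chain (destination != source)."""


def _as_space(space: CoordinateSpace | str) -> CoordinateSpace:
    return CoordinateSpace(space)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform mapping point coordinates source -> destination.

    Parameters
    ----------
    rotation
        3x3 orthonormal matrix with determinant +1.
    translation
        3-vector in mm.
    source, destination
        The named spaces the transform maps between.
    """

    rotation: np.ndarray
    translation: np.ndarray
    source: CoordinateSpace
    destination: CoordinateSpace

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tr = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-8):
            raise ValueError("rotation is not proper (det != +1)")
        rot = rot.copy()
        tr = tr.copy()
        rot.flags.writeable = False
        tr.flags.writeable = False
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)
        object.__setattr__(self, "source", _as_space(self.source))
        object.__setattr__(self, "destination", _as_space(self.destination))

    # -- constructors -----------------------------------------------------

    @classmethod
    def identity(
        cls,
        source: CoordinateSpace | str,
        destination: CoordinateSpace | str | None = None,
    ) -> "RigidTransform":
        if destination is None:
            destination = source
        return cls(np.eye(3), np.zeros(3), _as_space(source), _as_space(destination))

    @classmethod
    def from_quat(
        cls,
        quat_xyzw: Iterable[float],
        translation: Iterable[float],
        source: CoordinateSpace | str,
        destination: CoordinateSpace | str,
    ) -> "RigidTransform":
        """Build from a (possibly unnormalized) xyzw quaternion."""
        from scipy.spatial.transform import Rotation

        q = np.asarray(list(quat_xyzw), dtype=float)
        q = q / np.linalg.norm(q)
        return cls(
            Rotation.from_quat(q).as_matrix(),
            np.asarray(list(translation), dtype=float),
            _as_space(source),
            _as_space(destination),
        )

    # -- core operations ---------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map point(s) from source-space to destination-space coordinates."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, second: "RigidTransform") -> "RigidTransform":
        return compose(self, second)

    def inverse(self) -> "RigidTransform":
        return invert(self)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "source": self.source.value,
            "destination": self.destination.value,
            "rotation": [float(v) for v in self.rotation.ravel()],
            "translation_mm": [float(v) for v in self.translation],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            np.asarray(d["rotation"], dtype=float).reshape(3, 3),
            np.asarray(d["translation_mm"], dtype=float),
            d["source"],
            d["destination"],
        )

    @classmethod
    def from_json(cls, s: str) -> "RigidTransform":
        return cls.from_dict(json.loads(s))

    def isclose(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )


def compose(first: RigidTransform, second: RigidTransform) -> RigidTransform:
    """Chain two transforms: the result maps first.source -> second.destination.

    ``apply(compose(A, B), p) == apply(B, apply(A, p))``.
    """
    if first.destination != second.source:
        raise SpaceMismatchError(
            f"cannot chain {first.source.value}->{first.destination.value} "
            f"with {second.source.value}->{second.destination.value}"
        )
    rot = second.rotation @ first.rotation
    tr = second.rotation @ first.translation + second.translation
    return RigidTransform(rot, tr, first.source, second.destination)


def invert(t: RigidTransform) -> RigidTransform:
    """Inverse transform; source and destination are swapped."""
    rot = t.rotation.T
    return RigidTransform(rot, -rot @ t.translation, t.destination, t.source)


def apply(t: RigidTransform, points: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform.apply`."""
    return t.apply(points)


def rotation_about_axis(
    axis: Iterable[float], angle_deg: float
) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (degrees)."""
    from scipy.spatial.transform import Rotation

    ax = np.asarray(list(axis), dtype=float)
    ax = ax / np.linalg.norm(ax)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * ax).as_matrix()


@dataclass
class TransformChain:
    """Ordered list of transforms whose endpoints chain."""

    transforms: list[RigidTransform] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.transforms, self.transforms[1:]):
            if a.destination != b.source:
                raise SpaceMismatchError(
                    f"chain break: {a.destination.value} != {b.source.value}"
                )

    def collapse(self) -> RigidTransform:
        if not self.transforms:
            raise ValueError("empty chain")
        out = self.transforms[0]
        for t in self.transforms[1:]:
            out = compose(out, t)
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.collapse().apply(points)
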