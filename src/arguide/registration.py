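"""Point-to-point rigid registration and the FLE/FRE/TRE error budget.

The guidance system links the image volume to the tracked patient frame by a
least-squares rigid fit on seven corresponding fiducial markers.  This module
provides that fit (Kabsch/Umeyama, SVD-based, reflection-corrected) plus the
standard error-budget calculus around it:

* FLE (fiducial localization error): RMS error of measuring one fiducial.
* FRE (fiducial registration error): RMS residual after the best rigid fit,
  the quantity a navigation system can actually report.
* TRE (target registration error): displacement of a non-fiducial target
  induced by registration error — the quantity that matters clinically.

For isotropic zero-mean Gaussian localization noise applied to one space,
``E[FRE^2] = (1 - 2/N) * FLE^2``, which lets a simulation be calibrated from
a reported FRE.  The closed-form RMS TRE about the fiducial principal axes,

    TRE^2(r) = FLE^2 / N * (1 + (1/3) * sum_k d_k^2 / f_k^2),

(d_k: target distance from principal axis k; f_k: RMS fiducial distance from
axis k) is ill-conditioned when the fiducials are coplanar — as they are on a
flat marker plate — so Monte-Carlo prediction is the default and the closed
form refuses degenerate configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CoordinateSpace, RigidTransform

__all__ = [
    "FiducialSet",
    "RegistrationResult",
    "TrePrediction",
    "TreMethod",
    "DegenerateConfigurationError",
    "LabelMismatchError",
    "register_points",
    "estimate_fle_from_fre",
    "expected_fre_from_fle",
    "predict_tre",
    "simulate_fre",
    "simulate_target_errors",
]


class DegenerateConfigurationError(ValueError):
    """Fiducial configuration unusable for the requested computation."""


class LabelMismatchError(ValueError):
    """Source and target fiducial sets do not share the same labels."""


@dataclass(frozen=True)
class FiducialSet:
    """Labeled 3-D points (mm) in a named coordinate space.

    Requires at least three non-collinear points with unique labels —
    the minimum for an unambiguous rigid registration.
    """

    labels: tuple[str, ...]
    points: np.ndarray  # (N, 3) mm
    space: CoordinateSpace

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        pts = np.asarray(self.points, dtype=float).reshape(len(labels), 3).copy()
        if len(labels) < 3:
            raise DegenerateConfigurationError("need at least 3 fiducials")
        if len(set(labels)) != len(labels):
            raise ValueError("fiducial labels must be unique")
        centered = pts - pts.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[1] < 1e-9 * sv[0] and sv[2] < 1e-9 * sv[0]:
            raise DegenerateConfigurationError("fiducials are collinear")
        pts.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "space", CoordinateSpace(self.space))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def ordered_like(self, other: "FiducialSet") -> "FiducialSet":
        """Return a copy with rows reordered to match ``other``'s labels."""
        if set(self.labels) != set(other.labels):
            raise LabelMismatchError(
                f"labels differ: {sorted(self.labels)} vs {sorted(other.labels)}"
            )
        idx = [self.labels.index(lab) for lab in other.labels]
        return FiducialSet(other.labels, self.points[idx], self.space)

    def transformed(self, t: RigidTransform) -> "FiducialSet":
        return FiducialSet(self.labels, t.apply(self.points), t.destination)

    def is_coplanar(self, tol_mm: float = 1e-6) -> bool:
        centered = self.points - self.centroid
        eigvals = np.linalg.eigvalsh(centered.T @ centered / len(self))
        extents = np.sqrt(np.maximum(eigvals, 0.0))
        return bool(extents[0] <= tol_mm)

    # -- CSV interface: header `label,x_mm,y_mm,z_mm,space` ---------------

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "label": self.labels,
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "z_mm": self.points[:, 2],
                "space": self.space.value,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FiducialSet":
        df = pd.read_csv(path)
        required = {"label", "x_mm", "y_mm", "z_mm", "space"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"fiducial CSV missing columns: {sorted(missing)}")
        spaces = set(df["space"])
        if len(spaces) != 1:
            raise ValueError("fiducial CSV mixes coordinate spaces")
        return cls(
            tuple(df["label"].astype(str)),
            df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
            CoordinateSpace(spaces.pop()),
        )


@dataclass(frozen=True)
class RegistrationResult:
    """Rigid fit plus its residual summary."""

    transform: RigidTransform
    fre_mm: float
    per_fiducial_residuals_mm: np.ndarray

    def __post_init__(self) -> None:
        res = np.asarray(self.per_fiducial_residuals_mm, dtype=float)
        object.__setattr__(self, "per_fiducial_residuals_mm", res)
        # contract: FRE is the RMS of the per-fiducial residuals
        assert abs(self.fre_mm - float(np.sqrt(np.mean(res**2)))) < 1e-12


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit mapping src -> dst (both (N,3)).

    Returns (R, t) minimizing sum ||R p_i + t - q_i||^2, with the reflection
    corrected through the sign of the determinant.
    """
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, dc - rot @ sc


def register_points(source: FiducialSet, target: FiducialSet) -> RegistrationResult:
    """Least-squares rigid registration of corresponding fiducial sets.

    Correspondence is by label; point order need not match.  The returned
    transform maps ``source.space`` coordinates into ``target.space``.
    """
    src = source.ordered_like(target)
    rot, tr = _kabsch(src.points, target.points)
    transform = RigidTransform(rot, tr, src.space, target.space)
    residuals = np.linalg.norm(transform.apply(src.points) - target.points, axis=1)
    fre = float(np.sqrt(np.mean(residuals**2)))
    return RegistrationResult(transform, fre, residuals)


def estimate_fle_from_fre(fre_mm: float, n_fiducials: int) -> float:
    """Invert E[FRE^2] = (1 - 2/N) FLE^2 to calibrate FLE from a reported FRE."""
    if n_fiducials <= 2:
        raise ValueError("FLE from FRE undefined for N <= 2")
    if fre_mm < 0:
        raise ValueError("FRE must be non-negative")
    return float(fre_mm * np.sqrt(n_fiducials / (n_fiducials - 2)))


def expected_fre_from_fle(fle_mm: float, n_fiducials: int) -> float:
    """Expected RMS FRE for a given FLE: FRE = FLE * sqrt(1 - 2/N)."""
    if n_fiducials <= 2:
        raise ValueError("undefined for N <= 2")
    return float(fle_mm * np.sqrt(1.0 - 2.0 / n_fiducials))


class TreMethod(str, Enum):
    CLOSED_FORM = "CLOSED_FORM"
    MONTE_CARLO = "MONTE_CARLO"


@dataclass(frozen=True)
class TrePrediction:
    target_point: np.ndarray
    tre_rms_mm: float
    method: TreMethod

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "target_point", np.asarray(self.target_point, dtype=float)
        )
        assert self.tre_rms_mm >= 0


def _batch_rigid_fit(
    src: np.ndarray, dst: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Kabsch over a stack of replicates.

    src: (R, N, 3) noisy source sets; dst: (N, 3) fixed target set.
    Returns rotations (R, 3, 3) and translations (R, 3) mapping src -> dst.
    """
    sc = src.mean(axis=1, keepdims=True)
    dc = dst.mean(axis=0)
    h = np.einsum("rni,nj->rij", src - sc, dst - dc)
    u, _, vt = np.linalg.svd(h)
    v = vt.transpose(0, 2, 1)
    det = np.linalg.det(v @ u.transpose(0, 2, 1))
    v_corr = v.copy()
    v_corr[:, :, 2] *= det[:, None]
    rots = v_corr @ u.transpose(0, 2, 1)
    trs = dc - np.einsum("rij,rj->ri", rots, sc[:, 0, :])
    return rots, trs


def _noise_sigma(fle_mm: float) -> float:
    # isotropic model: FLE^2 = 3 sigma^2 per coordinate axis
    return fle_mm / np.sqrt(3.0)


def simulate_fre(
    fiducials: FiducialSet,
    fle_mm: float,
    n_reps: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Per-replicate FRE of registering noisy copies of a fiducial set.

    Isotropic Gaussian noise with per-axis sigma FLE/sqrt(3) is added to the
    source-side measurements; each replicate is registered back to the true
    configuration and its RMS residual recorded.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pts = fiducials.points
    noisy = pts[None, :, :] + rng.normal(
        scale=_noise_sigma(fle_mm), size=(n_reps, *pts.shape)
    )
    rots, trs = _batch_rigid_fit(noisy, pts)
    mapped = np.einsum("rij,rnj->rni", rots, noisy) + trs[:, None, :]
    res = np.linalg.norm(mapped - pts[None, :, :], axis=2)
    return np.sqrt(np.mean(res**2, axis=1))


def simulate_target_errors(
    fiducials: FiducialSet,
    fle_mm: float,
    targets: np.ndarray,
    n_reps: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Monte-Carlo TRE samples: (n_reps, n_targets) displacement norms (mm).

    Each replicate perturbs the fiducials, refits the rigid transform, maps
    the target point(s) through it and records the displacement from truth.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tgt = np.atleast_2d(np.asarray(targets, dtype=float))
    pts = fiducials.points
    noisy = pts[None, :, :] + rng.normal(
        scale=_noise_sigma(fle_mm), size=(n_reps, *pts.shape)
    )
    rots, trs = _batch_rigid_fit(noisy, pts)
    mapped = np.einsum("rij,tj->rti", rots, tgt) + trs[:, None, :]
    return np.linalg.norm(mapped - tgt[None, :, :], axis=2)


def _closed_form_tre(
    fiducials: FiducialSet, fle_mm: float, target: np.ndarray
) -> float:
    pts = fiducials.points - fiducials.centroid
    n = len(fiducials)
    cov = pts.T @ pts / n
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending; mean squared extents
    extents = np.sqrt(np.maximum(eigvals, 0.0))
    if np.any(extents <= 1e-6):
        raise DegenerateConfigurationError(
            "closed-form TRE is ill-conditioned for (near-)coplanar fiducials; "
            "use MONTE_CARLO"
        )
    rel = np.asarray(target, dtype=float) - fiducials.centroid
    coords = eigvecs.T @ rel
    # d_k^2: squared distance from principal axis k; f_k^2: mean squared
    # fiducial distance from axis k = sum of the other two eigenvalues
    d2 = np.array([np.sum(coords**2) - coords[k] ** 2 for k in range(3)])
    f2 = np.array([eigvals.sum() - eigvals[k] for k in range(3)])
    return float(np.sqrt(fle_mm**2 / n * (1.0 + (d2 / f2).sum() / 3.0)))


def predict_tre(
    fiducials: FiducialSet,
    fle_mm: float,
    target: np.ndarray,
    method: TreMethod | str = TreMethod.MONTE_CARLO,
    n_reps: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> TrePrediction:
    """Predict the RMS target registration error at ``target``.

    MONTE_CARLO (default) works for any configuration, including the coplanar
    marker plate; CLOSED_FORM uses the principal-axis formula and raises
    :class:`DegenerateConfigurationError` on coplanar sets.
    """
    if fle_mm < 0:
        raise ValueError("FLE must be non-negative")
    method = TreMethod(method)
    target = np.asarray(target, dtype=float).reshape(3)
    if fle_mm == 0.0:
        return TrePrediction(target, 0.0, method)
    if method is TreMethod.CLOSED_FORM:
        return TrePrediction(target, _closed_form_tre(fiducials, fle_mm, target), method)
    errs = simulate_target_errors(fiducials, fle_mm, target, n_reps, seed)
    return TrePrediction(target, float(np.sqrt(np.mean(errs**2))), method)
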