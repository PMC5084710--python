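"""Meristem reference frame, plane fitting and the two wall-orientation angles.

The orientation of a new cell wall is summarised by two angles measured on
the *normal* of its best-fitting plane (this normal-based convention is used
consistently; note some descriptions of wall orientation speak of the plane
itself, which is the complementary angle):

* ``angle_to_axis`` — angle between the wall normal and the stem main axis.
  A transversal wall (plane perpendicular to the axis, as typical of the rib
  meristem) scores near 0°; a wall plane containing the axis scores 90°.
* ``radial_angle`` — angle between the wall normal and the radial direction
  at the wall's centre of mass (the shortest line from the centre of mass to
  the main axis). A wall facing the central axis scores near 0°; a wall
  containing the radial direction ("radially oriented" division) scores 90°.

Both angles are folded into [0, 90]° because a plane normal has no sign.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "MeristemFrame",
    "PlaneFit",
    "DegenerateFitError",
    "fit_plane",
    "angle_to_axis",
    "radial_angle",
    "depth_and_radius",
    "frame_from_volume",
]

_RANK_RTOL = 1e-12


class DegenerateFitError(ValueError):
    """Raised when a plane cannot be fitted (too few / collinear points)."""


@dataclasses.dataclass(frozen=True)
class MeristemFrame:
    """Summit point (μm, xyz) and unit main-axis direction.

    The axis points from the stem base toward the summit. Depth below the
    summit and radius from the axis are measured with
    :func:`depth_and_radius`.
    """

    summit: np.ndarray
    axis: np.ndarray

    def __post_init__(self):
        summit = np.asarray(self.summit, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        if summit.shape != (3,) or not np.all(np.isfinite(summit)):
            raise ValueError(f"summit must be a finite 3-vector, got {self.summit}")
        norm = np.linalg.norm(axis)
        if axis.shape != (3,) or not np.isfinite(norm) or norm == 0:
            raise ValueError(f"axis must be a nonzero 3-vector, got {self.axis}")
        object.__setattr__(self, "summit", summit)
        object.__setattr__(self, "axis", axis / norm)


@dataclasses.dataclass(frozen=True)
class PlaneFit:
    """Best-fitting plane: unit normal, centroid (μm) and a planarity score.

    ``planarity`` is the ratio of the smallest to the middle eigenvalue of
    the centered second-moment matrix: 0 for exactly coplanar points, → 1
    for an isotropic cloud.
    """

    normal: np.ndarray
    centroid: np.ndarray
    planarity: float


def fit_plane(points: Sequence | np.ndarray, min_points: int = 4) -> PlaneFit:
    """Fit the least-scatter plane through a 3D point cloud.

    The normal is the eigenvector of the smallest eigenvalue of the centered
    second-moment matrix; its sign is unspecified (downstream angles are
    sign-folded). Raises :class:`DegenerateFitError` for fewer than
    ``min_points`` points or a point set of rank < 2 (collinear).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must be (n, 3), got {pts.shape}")
    if len(pts) < min_points:
        raise DegenerateFitError(f"{len(pts)} points < min_points={min_points}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    moment = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(moment)  # ascending
    if evals[1] <= _RANK_RTOL * max(evals[2], 1e-300):
        raise DegenerateFitError("points are collinear (rank < 2)")
    planarity = float(np.clip(evals[0] / evals[1], 0.0, 1.0))
    normal = evecs[:, 0]
    return PlaneFit(normal=normal, centroid=centroid, planarity=planarity)


def _folded_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees, folded to [0, 90], between two unit vectors."""
    c = abs(float(np.dot(u, v)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def angle_to_axis(fit: PlaneFit, frame: MeristemFrame) -> float:
    """Angle (deg, [0, 90]) between the wall normal and the stem main axis."""
    return _folded_angle_deg(fit.normal, frame.axis)


def radial_angle(fit: PlaneFit, frame: MeristemFrame, min_radius: float = 1.0) -> float:
    """Angle (deg, [0, 90]) between the wall normal and the radial direction.

    The radial direction is the component of ``centroid - summit``
    orthogonal to the axis, normalised. Returns NaN (undefined) when the
    centroid lies within ``min_radius`` μm of the main axis, where the
    radial direction is ill-defined.
    """
    v = fit.centroid - frame.summit
    v_perp = v - np.dot(v, frame.axis) * frame.axis
    r = np.linalg.norm(v_perp)
    if r < min_radius:
        return float("nan")
    return _folded_angle_deg(fit.normal, v_perp / r)


def depth_and_radius(point: Sequence | np.ndarray, frame: MeristemFrame) -> tuple[float, float]:
    """Axial depth below the summit and radial distance from the main axis (μm).

    ``depth = (summit - point) · axis`` is positive below the summit;
    ``radius`` is the distance from the point to the line through the summit
    along the axis.
    """
    p = np.asarray(point, dtype=float)
    d = p - frame.summit
    depth = -float(np.dot(d, frame.axis))
    perp = d - np.dot(d, frame.axis) * frame.axis
    return depth, float(np.linalg.norm(perp))


def frame_from_volume(vol, axis_xyz: Sequence[float] = (0.0, 0.0, 1.0)) -> MeristemFrame:
    """Default frame for a labelled volume: user axis, summit from the tissue.

    The summit is the mean centre of the non-background voxels whose
    projection onto the axis is within half the smallest voxel size of the
    maximum — i.e. the highest tissue voxels along the axis.
    """
    axis = np.asarray(axis_xyz, dtype=float)
    axis = axis / np.linalg.norm(axis)
    zz, yy, xx = np.nonzero(vol.labels != vol.background_label)
    sz, sy, sx = vol.spacing
    centers = np.column_stack([(xx + 0.5) * sx, (yy + 0.5) * sy, (zz + 0.5) * sz])
    proj = centers @ axis
    tol = 0.5 * min(vol.spacing)
    top = centers[proj >= proj.max() - tol]
    return MeristemFrame(summit=top.mean(axis=0), axis=axis)
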