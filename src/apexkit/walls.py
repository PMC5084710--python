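"""Cell-cell facet extraction and new-wall calling.

A *facet* is the shared interface between two adjacent cells in a labelled
volume, found by 6-connectivity (shared voxel faces only). After a
cross-linking cell-wall stain (e.g. modified pseudo-Schiff propidium
iodide), recently synthesised walls are thinner and fluoresce less, so a
facet is called a *new wall* when its mean stain density is the weakest
among the facets of **both** adjacent cells. This mutual-minimum rule
recovers recent division interfaces from a single fixed time point.

All physical quantities are in micrometres (areas μm²); signal density is
in the arbitrary units of the intensity volume.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .geometry import (
    DegenerateFitError,
    MeristemFrame,
    PlaneFit,
    angle_to_axis,
    depth_and_radius,
    fit_plane,
    radial_angle,
)
from .volumes import IntensityVolume, LabeledVolume

__all__ = ["Facet", "extract_facets", "call_new_walls", "detect_divisions"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class Facet:
    """The interface between two adjacent cells (``cell_a < cell_b``).

    ``face_voxels`` holds the flanking voxel index pairs (n, 2, 3) in
    (z, y, x) order, ``face_axes`` the array axis each face is normal to.
    ``face_points`` are the face-midpoint coordinates (n, 3) in μm, xyz
    order, and ``face_areas`` the per-face physical areas.
    """

    cell_a: int
    cell_b: int
    face_voxels: np.ndarray
    face_axes: np.ndarray
    face_points: np.ndarray
    face_areas: np.ndarray
    area: float
    centroid: np.ndarray
    signal_density: float
    eligible: bool
    plane: PlaneFit | None = None
    angle_to_axis: float = float("nan")
    radial_angle: float = float("nan")
    region: str = "NONE"
    is_new_wall: bool = False

    @property
    def pair(self) -> tuple[int, int]:
        return (self.cell_a, self.cell_b)


def _face_elements(labels: np.ndarray):
    """All 6-connected voxel faces between differing labels.

    Returns (lab_a, lab_b, idx_a (n,3), axis (n,)) with idx_b implied as
    idx_a + unit vector along axis.
    """
    la_all, lb_all, idx_all, ax_all = [], [], [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a = labels[tuple(sl_a)]
        b = labels[tuple(sl_b)]
        mask = a != b
        idx = np.argwhere(mask)
        la_all.append(a[mask])
        lb_all.append(b[mask])
        idx_all.append(idx)
        ax_all.append(np.full(len(idx), axis, dtype=np.int8))
    return (
        np.concatenate(la_all),
        np.concatenate(lb_all),
        np.concatenate(idx_all) if idx_all else np.empty((0, 3), int),
        np.concatenate(ax_all),
    )


def extract_facets(
    vol: LabeledVolume,
    intensity: IntensityVolume,
    min_face_elements: int = 5,
) -> list[Facet]:
    """One facet per unordered label pair sharing enough voxel faces.

    Pairs sharing fewer than ``min_face_elements`` faces are discarded
    (suppresses single-voxel segmentation noise). Facet area is the sum of
    the physical areas of its faces (spacing product of the two in-face
    axes), the centroid is the area-weighted mean of face midpoints, and
    the signal density is the area-weighted mean over faces of the mean
    intensity of the two flanking voxels. Facets touching the background
    are extracted but flagged ineligible for new-wall calling.
    """
    if vol.shape != intensity.shape:
        raise ValueError(f"volume shape {vol.shape} != intensity shape {intensity.shape}")
    labels = vol.labels
    if not (labels != vol.background_label).any():
        raise ValueError("empty segmentation: no non-background voxels")

    la, lb, idx_a, axes = _face_elements(labels)
    if len(la) == 0:
        return []

    sz, sy, sx = vol.spacing
    spacing_zyx = np.array([sz, sy, sx])
    # physical area of a face normal to each array axis
    face_area_by_axis = np.array([sy * sx, sz * sx, sz * sy])

    idx_b = idx_a.copy()
    idx_b[np.arange(len(idx_b)), axes] += 1

    vals = intensity.values
    inten = 0.5 * (vals[idx_a[:, 0], idx_a[:, 1], idx_a[:, 2]] + vals[idx_b[:, 0], idx_b[:, 1], idx_b[:, 2]])
    areas = face_area_by_axis[axes]

    # face midpoint in μm, xyz order: midway between the two voxel centers
    mid_zyx = (idx_a + 0.5) * spacing_zyx
    mid_zyx[np.arange(len(mid_zyx)), axes] += 0.5 * spacing_zyx[axes]
    pts_xyz = mid_zyx[:, ::-1].copy()

    lo = np.minimum(la, lb).astype(np.int64)
    hi = np.maximum(la, lb).astype(np.int64)
    key = lo * (labels.max() + 1) + hi
    order = np.argsort(key, kind="stable")
    key_s = key[order]
    uniq, starts, counts = np.unique(key_s, return_index=True, return_counts=True)

    bg = vol.background_label
    facets: list[Facet] = []
    voxpair = np.stack([idx_a, idx_b], axis=1)
    for s, c in zip(starts, counts):
        if c < min_face_elements:
            continue
        sel = order[s : s + c]
        a = int(lo[sel[0]])
        b = int(hi[sel[0]])
        w = areas[sel]
        area = float(w.sum())
        centroid = (pts_xyz[sel] * w[:, None]).sum(axis=0) / area
        density = float((inten[sel] * w).sum() / area)
        facets.append(
            Facet(
                cell_a=a,
                cell_b=b,
                face_voxels=voxpair[sel].astype(np.int32),
                face_axes=axes[sel].copy(),
                face_points=pts_xyz[sel],
                face_areas=w,
                area=area,
                centroid=centroid,
                signal_density=density,
                eligible=(a != bg and b != bg),
            )
        )
    return facets


def call_new_walls(facets: list[Facet], tie_tol: float = 1e-9) -> list[Facet]:
    """Flag facets whose density is the weakest for *both* adjacent cells.

    A facet ``f(a, b)`` is called iff its density is within a relative
    ``tie_tol`` of the minimum density over a's eligible facets AND over
    b's. Ties call every tied facet; facets touching the background are
    never called. Flags are set in place; the list is returned for
    chaining.
    """
    cell_min: dict[int, float] = {}
    for f in facets:
        if not f.eligible:
            continue
        for c in (f.cell_a, f.cell_b):
            if c not in cell_min or f.signal_density < cell_min[c]:
                cell_min[c] = f.signal_density
    for f in facets:
        if not f.eligible:
            f.is_new_wall = False
            continue
        thr_a = cell_min[f.cell_a] * (1.0 + tie_tol)
        thr_b = cell_min[f.cell_b] * (1.0 + tie_tol)
        f.is_new_wall = f.signal_density <= thr_a and f.signal_density <= thr_b
    return facets


def detect_divisions(
    vol: LabeledVolume,
    intensity: IntensityVolume,
    frame: MeristemFrame | None = None,
    min_face_elements: int = 5,
    tie_tol: float = 1e-9,
    min_fit_points: int = 4,
    min_radius: float = 1.0,
    regions=None,
) -> list[Facet]:
    """Full pipeline: extract facets, call new walls, orient every facet.

    Plane fitting uses the facet's face midpoints; facets with too few or
    collinear points keep NaN angles. When a frame is given, angles and
    (if ``regions`` is given) region labels are filled in; otherwise only
    the new-wall flags are set.
    """
    from .zonation import classify_point  # local import to avoid a cycle

    facets = extract_facets(vol, intensity, min_face_elements=min_face_elements)
    call_new_walls(facets, tie_tol=tie_tol)
    n_degenerate = 0
    for f in facets:
        if frame is not None and regions is not None:
            depth, radius = depth_and_radius(f.centroid, frame)
            f.region = classify_point(depth, radius, regions)
        try:
            f.plane = fit_plane(f.face_points, min_points=min_fit_points)
        except DegenerateFitError:
            n_degenerate += 1
            continue
        if frame is not None:
            f.angle_to_axis = angle_to_axis(f.plane, frame)
            f.radial_angle = radial_angle(f.plane, frame, min_radius=min_radius)
    n_called = sum(f.is_new_wall for f in facets)
    logger.info(
        "detect_divisions: %d facets, %d called as new walls, %d degenerate fits",
        len(facets),
        n_called,
        n_degenerate,
    )
    return facets
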