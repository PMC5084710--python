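"""Clonal (recombination-marked) sector alignment and measurement.

A sector is a clone of cells descended from one marked cell, recorded as
one manually placed landmark per cell (μm, xyz). Sectors from different
apices are brought into a common frame by a rigid transform that moves the
meristem summit to the origin and the stem main axis onto +z (azimuth is
left untouched: no azimuthal landmark exists). Each sector is then
summarised by its centre of mass, principal (main) axis, vertical and
radial angles, cell count, and main-axis length.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import MeristemFrame
from .zonation import RegionSpec, default_regions, mann_whitney_u

__all__ = [
    "Sector",
    "align_apex",
    "measure_sector",
    "project_sectors",
    "compare_sector_stats",
    "SECTOR_METRICS",
]

logger = logging.getLogger(__name__)

SECTOR_METRICS = ("vertical_angle", "sector_radial_angle", "n_cells", "length")


@dataclasses.dataclass
class Sector:
    """One measured clone, in aligned coordinates (summit at origin, axis +z)."""

    apex_id: str
    sector_id: str
    cell_points: np.ndarray  # (n, 3) aligned μm
    com: np.ndarray
    principal_axis: np.ndarray | None
    vertical_angle: float
    sector_radial_angle: float
    n_cells: int
    length: float


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking a unit vector onto +z.

    Rotates about the mutual perpendicular; an axis antiparallel to +z is
    mapped by a half-turn about x (fixed convention).
    """
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(axis, z))
    if c <= -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])  # half-turn about x
    v = np.cross(axis, z)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def align_apex(points: Sequence | np.ndarray, frame: MeristemFrame) -> np.ndarray:
    """Rigidly map apex coordinates into the common frame.

    Translates the summit to the origin, then rotates the main axis onto
    +z by the minimal rotation. Distances are preserved exactly (up to
    float round-off).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    R = _rotation_to_z(frame.axis)
    return (pts - frame.summit) @ R.T


def measure_sector(
    cell_points: Sequence | np.ndarray,
    apex_id: str = "",
    sector_id: str = "",
    min_radius: float = 1.0,
) -> Sector:
    """Measure a sector from its aligned landmarks (one point per cell).

    The principal (main) axis is the direction of greatest scatter of the
    landmarks (sign-folded); the vertical angle is measured against +z, the
    radial angle against the radial direction at the centre of mass
    (undefined within ``min_radius`` μm of the axis). Length is the extent
    (max - min) of the landmark projections on the principal axis. A
    single-point sector has an undefined axis, zero length and NaN angles.
    """
    pts = np.atleast_2d(np.asarray(cell_points, dtype=float))
    n = len(pts)
    if n < 1:
        raise ValueError("sector needs at least one landmark")
    com = pts.mean(axis=0)
    axis = None
    vertical = float("nan")
    radial = float("nan")
    length = 0.0
    if n >= 2:
        centered = pts - com
        moment = centered.T @ centered / n
        evals, evecs = np.linalg.eigh(moment)
        if evals[2] > 1e-12 * max(abs(evals).max(), 1.0) and evals[2] > 0:
            axis = evecs[:, 2]
            proj = centered @ axis
            length = float(proj.max() - proj.min())
            vertical = float(np.degrees(np.arccos(np.clip(abs(axis[2]), 0.0, 1.0))))
            r_vec = np.array([com[0], com[1], 0.0])
            r = np.linalg.norm(r_vec)
            if r >= min_radius:
                rhat = r_vec / r
                radial = float(
                    np.degrees(np.arccos(np.clip(abs(float(axis @ rhat)), 0.0, 1.0)))
                )
    return Sector(
        apex_id=apex_id,
        sector_id=sector_id,
        cell_points=pts,
        com=com,
        principal_axis=axis,
        vertical_angle=vertical,
        sector_radial_angle=radial,
        n_cells=n,
        length=length,
    )


def project_sectors(sectors: Sequence[Sector], mode: str = "vertical") -> dict[str, np.ndarray]:
    """2D projections of aligned sectors for plotting.

    ``vertical`` mode views along the axis (drop z → (x, y)). ``radial``
    mode projects each sector onto the plane through its centre of mass and
    the main axis, giving per-point (signed r, z); the sign follows the
    sector com's x-coordinate so left/right placement matches the vertical
    view. A com on the axis defaults to positive sign (with a warning).
    """
    if mode not in ("vertical", "radial"):
        raise ValueError(f"unknown projection mode {mode!r}")
    out: dict[str, np.ndarray] = {}
    for s in sectors:
        key = f"{s.apex_id}/{s.sector_id}"
        if mode == "vertical":
            out[key] = s.cell_points[:, :2].copy()
        else:
            com_xy = s.com[:2]
            r = np.linalg.norm(com_xy)
            if r < 1e-12:
                logger.warning("sector %s com on axis; radial sign defaults positive", key)
                rhat = np.array([1.0, 0.0])
                sign = 1.0
            else:
                rhat = com_xy / r
                sign = 1.0 if s.com[0] >= 0 else -1.0
            # signed distance along the com azimuth; left/right keyed to com x
            rr = s.cell_points[:, :2] @ rhat
            out[key] = np.column_stack([sign * rr, s.cell_points[:, 2]])
    return out


def sector_region(sector: Sector, regions: Sequence[RegionSpec] | None = None) -> str:
    """Zonation region of a sector's centre of mass (aligned frame)."""
    from .zonation import classify_point

    if regions is None:
        regions = default_regions()
    depth = -float(sector.com[2])  # aligned frame: summit at origin, axis +z
    radius = float(np.linalg.norm(sector.com[:2]))
    return classify_point(depth, radius, regions)


def compare_sector_stats(
    group_1: Sequence[Sector],
    group_2: Sequence[Sector],
    metric: str,
    regions: Sequence[RegionSpec] | None = None,
) -> dict[str, tuple[float, float, int, int]]:
    """Per-region Mann-Whitney comparison of one sector metric.

    Returns ``{region: (U, p, n1, n2)}``; regions empty in either group are
    skipped with a warning. NaN metric values (e.g. undefined angles) are
    dropped.
    """
    if metric not in SECTOR_METRICS:
        raise ValueError(f"metric must be one of {SECTOR_METRICS}, got {metric!r}")
    if regions is None:
        regions = default_regions()
    out = {}
    for spec in regions:
        v1 = np.array(
            [getattr(s, metric) for s in group_1 if sector_region(s, regions) == spec.name],
            dtype=float,
        )
        v2 = np.array(
            [getattr(s, metric) for s in group_2 if sector_region(s, regions) == spec.name],
            dtype=float,
        )
        v1, v2 = v1[np.isfinite(v1)], v2[np.isfinite(v2)]
        if len(v1) == 0 or len(v2) == 0:
            logger.warning("region %s empty in one group; skipped", spec.name)
            continue
        u, p = mann_whitney_u(v1, v2)
        out[spec.name] = (u, p, len(v1), len(v2))
    return out


def sectors_to_frame(sectors: Sequence[Sector]) -> pd.DataFrame:
    """Per-sector metrics as a tidy DataFrame (aligned com in xyz μm)."""
    rows = []
    for s in sectors:
        ax = s.principal_axis if s.principal_axis is not None else (np.nan, np.nan, np.nan)
        rows.append(
            {
                "apex_id": s.apex_id,
                "sector_id": s.sector_id,
                "com_x_um": s.com[0],
                "com_y_um": s.com[1],
                "com_z_um": s.com[2],
                "axis_x": ax[0],
                "axis_y": ax[1],
                "axis_z": ax[2],
                "vertical_angle_deg": s.vertical_angle,
                "radial_angle_deg": s.sector_radial_angle,
                "n_cells": s.n_cells,
                "length_um": s.length,
                "region": sector_region(s),
            }
        )
    return pd.DataFrame(rows)
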