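"""Co-registered label / wall-stain volumes and tabular IO.

Coordinate conventions owned here and used everywhere else in the package:

* Arrays are indexed ``(z, y, x)``, matching multi-page TIFF page order
  (page = z-slice).
* ``spacing`` is the per-axis voxel size in micrometres, given in the same
  ``(z, y, x)`` order.
* Voxel *centers* sit at ``(index + 0.5) * spacing``, so all physical
  coordinates are unambiguous at sub-voxel resolution.
* Every physical coordinate reported in output tables (centroids, summit,
  landmarks) is written in ``(x, y, z)`` order, in micrometres.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "LabeledVolume",
    "IntensityVolume",
    "read_volume_pair",
    "write_volume_pair",
    "write_facet_table",
    "read_facet_table",
    "FACET_TABLE_COLUMNS",
]


@dataclasses.dataclass(frozen=True)
class LabeledVolume:
    """A segmented 3D volume: integer cell labels on a (z, y, x) grid.

    ``background_label`` marks exterior / unsegmented space (default 0).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    background_label: int = 0

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {labels.dtype}")
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if not (labels != self.background_label).any():
            raise ValueError("volume contains no non-background voxel")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def cell_labels(self) -> np.ndarray:
        """Sorted unique non-background labels."""
        u = np.unique(self.labels)
        return u[u != self.background_label]


@dataclasses.dataclass(frozen=True)
class IntensityVolume:
    """Wall-stain signal on the same grid as a paired :class:`LabeledVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {values.shape}")
        if values.min() < 0:
            raise ValueError("intensity values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def read_volume_pair(
    label_path: str | Path,
    intensity_path: str | Path,
    spacing: Sequence[float],
    background_label: int = 0,
) -> tuple[LabeledVolume, IntensityVolume]:
    """Read a co-registered (labels, intensity) multi-page TIFF pair.

    ``spacing`` is (z, y, x) voxel size in micrometres. Raises on shape
    mismatch between the two stacks and on non-integer label data.
    """
    labels = tifffile.imread(str(label_path))
    values = tifffile.imread(str(intensity_path))
    labels = np.atleast_3d(labels)
    values = np.atleast_3d(values)
    if labels.ndim == 2:
        labels = labels[None]
    if values.ndim == 2:
        values = values[None]
    if labels.shape != values.shape:
        raise ValueError(
            f"label stack shape {labels.shape} does not match "
            f"intensity stack shape {values.shape}"
        )
    if not np.issubdtype(labels.dtype, np.integer):
        if np.allclose(labels, np.round(labels)):
            labels = np.round(labels).astype(np.int64)
        else:
            raise ValueError(f"label stack is not integer data (dtype {labels.dtype})")
    spacing = tuple(float(s) for s in spacing)
    vol = LabeledVolume(labels=labels, spacing=spacing, background_label=background_label)
    inten = IntensityVolume(values=values.astype(float), spacing=spacing)
    return vol, inten


def write_volume_pair(
    vol: LabeledVolume,
    inten: IntensityVolume,
    label_path: str | Path,
    intensity_path: str | Path,
) -> None:
    """Write a volume pair as multi-page TIFFs (labels uint16/32, intensity float32)."""
    labels = vol.labels
    dtype = np.uint16 if labels.max() < 2**16 else np.uint32
    tifffile.imwrite(str(label_path), labels.astype(dtype))
    tifffile.imwrite(str(intensity_path), inten.values.astype(np.float32))


#: Column order of the facet table written by :func:`write_facet_table`.
#: Coordinates in μm, xyz order; angles in degrees; undefined angles are
#: empty cells (NaN), never 0.
FACET_TABLE_COLUMNS = [
    "cell_a",
    "cell_b",
    "centroid_x_um",
    "centroid_y_um",
    "centroid_z_um",
    "area_um2",
    "n_faces",
    "signal_density",
    "normal_x",
    "normal_y",
    "normal_z",
    "planarity",
    "angle_to_axis_deg",
    "radial_angle_deg",
    "region",
    "eligible",
    "is_new_wall",
]


def facets_to_frame(facets) -> pd.DataFrame:
    """Convert a list of :class:`apexkit.walls.Facet` to a tidy DataFrame."""
    rows = []
    for f in facets:
        n = f.plane.normal if f.plane is not None else (np.nan, np.nan, np.nan)
        planarity = f.plane.planarity if f.plane is not None else np.nan
        rows.append(
            {
                "cell_a": f.cell_a,
                "cell_b": f.cell_b,
                "centroid_x_um": f.centroid[0],
                "centroid_y_um": f.centroid[1],
                "centroid_z_um": f.centroid[2],
                "area_um2": f.area,
                "n_faces": len(f.face_areas),
                "signal_density": f.signal_density,
                "normal_x": n[0],
                "normal_y": n[1],
                "normal_z": n[2],
                "planarity": planarity,
                "angle_to_axis_deg": f.angle_to_axis,
                "radial_angle_deg": f.radial_angle,
                "region": f.region,
                "eligible": f.eligible,
                "is_new_wall": f.is_new_wall,
            }
        )
    return pd.DataFrame(rows, columns=FACET_TABLE_COLUMNS)


def write_facet_table(facets, path: str | Path) -> None:
    """Write one CSV row per facet (header-only file for an empty list)."""
    df = facets_to_frame(facets)
    df.to_csv(path, index=False)


def read_facet_table(path: str | Path) -> pd.DataFrame:
    """Read a facet table written by :func:`write_facet_table`."""
    df = pd.read_csv(path)
    missing = [c for c in FACET_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"facet table {path} is missing columns {missing}")
    return df
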