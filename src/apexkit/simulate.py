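"""Seeded synthetic-data generators with ground truth.

Three forward models produce every input the analysis modules consume, so
the whole toolkit is testable without any real microscopy or sequencing
data:

* :func:`generate_meristem` — a dome-capped tessellated tissue volume with
  planted cell divisions of known 3D plane orientation and a wall-stain
  intensity volume in which recently formed walls are dimmer.
* :func:`generate_sectors` — clonal-sector landmark tables grown along
  known directions in randomly posed apex frames.
* :func:`generate_genome_and_peaks` — a toy genome with strand-aware gene
  models and three treatment + three control replicate peak sets carrying
  positionally biased true binding sites.

The generators aim for *detectability structure*, not biophysical realism:
cells are a nearest-seed space partition, wall brightness encodes wall age
as a monotone gradient (old walls bright, planted walls dim), and peaks are
placed in reserved genomic slots so the consensus rules have an exact known
answer. All randomness flows from a single seed; outputs are
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import MeristemFrame, depth_and_radius
from .peaks import GeneModel, PeakCall, _zone_segments, write_gff3, write_narrowpeak
from .peaks import ZONE_DOWNSTREAM, ZONE_PROMOTER, ZONE_TRANSCRIBED
from .volumes import IntensityVolume, LabeledVolume
from .walls import _face_elements
from .zonation import RegionSpec, classify_point, default_regions

__all__ = [
    "OrientationSpec",
    "MeristemSimParams",
    "generate_meristem",
    "evaluate_detection",
    "SectorSimParams",
    "generate_sectors",
    "GenomeSimParams",
    "GenomeSim",
    "generate_genome_and_peaks",
]

logger = logging.getLogger(__name__)

# Old-wall brightness follows a wall-age potential: tissue grows from the
# summit, so walls deeper below it are older and brighter; a small generic
# lateral component breaks ties. A predominantly vertical potential has a
# unique local minimum on the cell-adjacency graph — the summit cell —
# and the generator divides that cell, so every "weakest wall of my
# neighbourhood" chain terminates at a planted division instead of at a
# mutually-weakest mature pair. The margin-aware brightening pass below
# removes the residual near-ties that voxel noise could flip.
_AGE_DIR = np.array([0.06, 0.04, -1.0]) / np.linalg.norm([0.06, 0.04, -1.0])


@dataclasses.dataclass(frozen=True)
class OrientationSpec:
    """Division-plane normal distribution for one region.

    ``mean_angle_to_axis`` / ``sd_angle`` parameterise a folded normal on
    the angle between the wall normal and the stem axis (degrees).
    ``azimuth`` is either ``"uniform"`` or a mean azimuth in degrees (0 =
    radial direction, 90 = tangential), with ``sd_azimuth`` jitter.
    """

    mean_angle_to_axis: float
    sd_angle: float = 10.0
    azimuth: float | str = "uniform"
    sd_azimuth: float = 10.0


def _default_orientations() -> dict[str, OrientationSpec]:
    # Wild-type-like pattern: transversal divisions in the rib-meristem
    # core, anticlinal walls of varied azimuth in the apical region and
    # the rib-meristem periphery.
    return {
        "AR": OrientationSpec(90.0, 10.0, "uniform"),
        "RC": OrientationSpec(0.0, 10.0, "uniform"),
        "RP": OrientationSpec(90.0, 10.0, "uniform"),
    }


@dataclasses.dataclass
class MeristemSimParams:
    """Forward-model parameters for the synthetic meristem volume.

    Defaults give a dome large enough to contain the three standard
    zonation windows (radius to 50 μm, depth to 60 μm below the summit),
    cells of ~8 μm diameter sampled at 1 μm in all directions (fine enough
    to resolve wall tilts of a few degrees), a new/old wall intensity
    ratio of 0.5 and voxel noise of 10 % of the old-wall intensity.
    Anisotropic spacing is fully supported; the default is isotropic.
    """

    dome_radius: float = 55.0
    dome_height: float = 25.0  # drop of the dome cap from summit to rim
    total_height: float = 66.0
    cell_diameter: float = 8.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (z, y, x) μm
    n_divisions: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"AR": 30, "RC": 40, "RP": 30}
    )
    orientations: Mapping[str, OrientationSpec] = dataclasses.field(
        default_factory=_default_orientations
    )
    old_intensity: float = 100.0
    intensity_ratio: float = 0.5
    noise_sd: float = 0.1  # fraction of old_intensity
    age_gain: float = 4.5  # brightness range of the wall-age gradient
    guard_k: float = 2.5  # noise-margin (in SD units) kept around cell minima
    seed: int = 0
    min_daughter_voxels: int = 12
    min_interface_faces: int = 6
    min_face_elements: int = 5  # used by the internal consistency pass

    def __post_init__(self):
        if not (0 < self.intensity_ratio <= 1):
            raise ValueError("intensity_ratio must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def small(cls, seed: int = 0, n_divisions: Mapping[str, int] | None = None, **kw):
        """A tiny apical dome (<= ~50 cells) for oracle-equivalence tests."""
        defaults = dict(
            dome_radius=13.0,
            dome_height=6.0,
            total_height=17.0,
            cell_diameter=7.0,
            spacing=(1.5, 1.5, 1.5),
            n_divisions=n_divisions if n_divisions is not None else {"AR": 5},
            seed=seed,
        )
        defaults.update(kw)
        return cls(**defaults)


def _sample_normal_xyz(
    spec: OrientationSpec, rhat: np.ndarray, that: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    theta = abs(rng.normal(spec.mean_angle_to_axis, spec.sd_angle))
    if theta > 90.0:
        theta = 180.0 - theta if theta <= 180 else theta % 90
    theta = np.radians(np.clip(theta, 0.0, 90.0))
    if spec.azimuth == "uniform":
        psi = rng.uniform(0.0, 2 * np.pi)
    else:
        psi = np.radians(rng.normal(float(spec.azimuth), spec.sd_azimuth))
    n = np.array(
        [
            np.sin(theta) * (np.cos(psi) * rhat[0] + np.sin(psi) * that[0]),
            np.sin(theta) * (np.cos(psi) * rhat[1] + np.sin(psi) * that[1]),
            np.cos(theta),
        ]
    )
    return n / np.linalg.norm(n)


def _facet_table(labels: np.ndarray, spacing: tuple[float, float, float]):
    """Vectorised facet bookkeeping for the intensity forward model.

    Returns face-level arrays plus the facet grouping (pair lo/hi, inverse
    map face→facet, per-facet counts).
    """
    la, lb, idx_a, axes = _face_elements(labels)
    idx_b = idx_a.copy()
    idx_b[np.arange(len(idx_b)), axes] += 1
    lo = np.minimum(la, lb).astype(np.int64)
    hi = np.maximum(la, lb).astype(np.int64)
    key = lo * (int(labels.max()) + 1) + hi
    uniq, inverse, counts = np.unique(key, return_inverse=True, return_counts=True)
    pair_lo = uniq // (int(labels.max()) + 1)
    pair_hi = uniq % (int(labels.max()) + 1)
    sz, sy, sx = spacing
    area_by_axis = np.array([sy * sx, sz * sx, sz * sy])
    face_area = area_by_axis[axes]
    return idx_a, idx_b, inverse, counts, pair_lo, pair_hi, face_area


def generate_meristem(
    params: MeristemSimParams,
) -> tuple[LabeledVolume, IntensityVolume, MeristemFrame, pd.DataFrame]:
    """Generate a labelled dome volume, stain volume, frame and truth table.

    The tissue mask is a paraboloid-capped cylinder; cells are the
    nearest-seed partition of the mask; per-region mother cells are split
    by a plane through their centroid with a normal drawn from the
    region's orientation distribution. Old walls get brightness
    0.9-1.1 × ``old_intensity`` following a positional gradient, planted
    walls ``intensity_ratio`` × ``old_intensity``, and the construction is
    checked (and locally brightened where needed) so that, noise-free, the
    weakest-for-both-cells rule calls exactly the planted set. Gaussian
    voxel noise is added last.

    The truth table lists each planted wall's daughter-label pair, region,
    true plane normal (xyz) and true orientation angles.
    """
    rng = np.random.default_rng(params.seed)
    sz, sy, sx = params.spacing
    R, H, hd = params.dome_radius, params.total_height, params.dome_height
    pad = 2.0
    nz = int(np.ceil((H + pad) / sz))
    ny = int(np.ceil((2 * R + 2 * pad) / sy))
    nx = int(np.ceil((2 * R + 2 * pad) / sx))
    cx = cy = R + pad

    z = (np.arange(nz) + 0.5) * sz
    y = (np.arange(ny) + 0.5) * sy
    x = (np.arange(nx) + 0.5) * sx
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    rr = np.hypot(xx - cx, yy - cy)
    top = H - hd * (rr / R) ** 2
    mask = (rr <= R) & (zz <= top) & (zz >= pad / 2)

    coords_zyx = np.argwhere(mask)
    centers_xyz = np.column_stack(
        [
            (coords_zyx[:, 2] + 0.5) * sx,
            (coords_zyx[:, 1] + 0.5) * sy,
            (coords_zyx[:, 0] + 0.5) * sz,
        ]
    )
    tissue_volume = len(coords_zyx) * sz * sy * sx
    cell_volume = np.pi / 6.0 * params.cell_diameter**3
    n_cells = max(2, int(round(tissue_volume / cell_volume)))
    if n_cells > len(coords_zyx) // 4:
        raise ValueError("cell diameter too small/large for the dome voxel grid")
    seed_idx = rng.choice(len(coords_zyx), size=n_cells, replace=False)
    tree = cKDTree(centers_xyz[seed_idx])
    _, assign = tree.query(centers_xyz, k=1)

    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    labels[tuple(coords_zyx.T)] = assign + 1

    # per-cell voxel lists and centroids
    order = np.argsort(assign, kind="stable")
    counts = np.bincount(assign, minlength=n_cells)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    cell_vox: dict[int, np.ndarray] = {}
    cell_centroid: dict[int, np.ndarray] = {}
    for c in range(n_cells):
        sel = order[offsets[c] : offsets[c + 1]]
        cell_vox[c + 1] = coords_zyx[sel]
        cell_centroid[c + 1] = centers_xyz[sel].mean(axis=0)

    summit = np.array([cx, cy, H])
    frame = MeristemFrame(summit=summit, axis=np.array([0.0, 0.0, 1.0]))
    regions = default_regions()

    cell_region = {
        c: classify_point(*depth_and_radius(cell_centroid[c], frame), regions)
        for c in cell_vox
    }

    strides = np.array([ny * nx, nx, 1], dtype=np.int64)
    next_label = n_cells + 1
    truth_rows = []
    divided: set[int] = set()
    # the age-potential minimum (the summit cell) must divide so that the
    # weakest-wall chains of undivided cells terminate at a planted wall
    potential = {c: float(cell_centroid[c] @ _AGE_DIR) for c in cell_vox}
    summit_cell = min(potential, key=potential.get)
    for region_name, n_div in params.n_divisions.items():
        spec = params.orientations.get(region_name)
        if spec is None:
            raise ValueError(f"no orientation spec for region {region_name!r}")
        candidates = [
            c
            for c in cell_vox
            if cell_region[c] == region_name
            and c not in divided
            and len(cell_vox[c]) >= 2 * params.min_daughter_voxels
        ]
        rng.shuffle(candidates)
        if summit_cell in candidates:
            candidates.remove(summit_cell)
            candidates.insert(0, summit_cell)
        done = 0
        for mother in candidates:
            if done >= n_div:
                break
            vox = cell_vox[mother]
            ctr = cell_centroid[mother]
            pts = np.column_stack(
                [(vox[:, 2] + 0.5) * sx, (vox[:, 1] + 0.5) * sy, (vox[:, 0] + 0.5) * sz]
            )
            v = ctr - summit
            v[2] = 0.0
            r = np.linalg.norm(v[:2])
            if r < 1e-6:
                az = rng.uniform(0, 2 * np.pi)
                rhat = np.array([np.cos(az), np.sin(az), 0.0])
            else:
                rhat = np.array([v[0] / r, v[1] / r, 0.0])
            that = np.array([-rhat[1], rhat[0], 0.0])
            ok = False
            for _ in range(4):
                normal = _sample_normal_xyz(spec, rhat, that, rng)
                side = (pts - ctr) @ normal > 0
                na, nb = int(side.sum()), int((~side).sum())
                if min(na, nb) < params.min_daughter_voxels:
                    continue
                flat = vox @ strides
                a_set = flat[side]
                b_set = flat[~side]
                nbr = (b_set[:, None] + np.array([strides[0], -strides[0], strides[1], -strides[1], 1, -1])).ravel()
                n_faces = int(np.isin(nbr, a_set).sum())
                if n_faces < max(params.min_interface_faces, params.min_face_elements):
                    continue
                ok = True
                break
            if not ok:
                continue
            daughter = next_label
            next_label += 1
            dvox = vox[side]
            labels[tuple(dvox.T)] = daughter
            cell_vox[daughter] = dvox
            cell_vox[mother] = vox[~side]
            cell_centroid[daughter] = pts[side].mean(axis=0)
            cell_centroid[mother] = pts[~side].mean(axis=0)
            for c in (mother, daughter):
                cell_region[c] = classify_point(*depth_and_radius(cell_centroid[c], frame), regions)
            divided.add(mother)
            divided.add(daughter)
            ata = float(np.degrees(np.arccos(np.clip(abs(normal[2]), 0, 1))))
            rad = float(np.degrees(np.arccos(np.clip(abs(normal @ rhat), 0, 1))))
            truth_rows.append(
                {
                    "cell_a": min(mother, daughter),
                    "cell_b": max(mother, daughter),
                    "region": region_name,
                    "normal_x": normal[0],
                    "normal_y": normal[1],
                    "normal_z": normal[2],
                    "angle_to_axis_true": ata,
                    "radial_angle_true": rad,
                }
            )
            done += 1
        if done < n_div:
            raise ValueError(
                f"could only plant {done}/{n_div} divisions in region {region_name}; "
                "enlarge the dome or reduce n_divisions"
            )

    truth = pd.DataFrame(truth_rows)
    intensity = _paint_intensity(labels, params, truth, rng)
    vol = LabeledVolume(labels=labels, spacing=params.spacing, background_label=0)
    inten = IntensityVolume(values=intensity, spacing=params.spacing)
    return vol, inten, frame, truth


def _paint_intensity(
    labels: np.ndarray,
    params: MeristemSimParams,
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """Wall-stain forward model (see :func:`generate_meristem`)."""
    sz, sy, sx = params.spacing
    idx_a, idx_b, inverse, counts, pair_lo, pair_hi, face_area = _facet_table(
        labels, params.spacing
    )
    n_facets = len(pair_lo)
    planted = set(zip(truth["cell_a"], truth["cell_b"])) if len(truth) else set()
    planted_mask = np.array(
        [(int(a), int(b)) in planted for a, b in zip(pair_lo, pair_hi)]
    )

    # wall-age brightness per facet: older (deeper) walls are brighter
    max_lab = int(labels.max())
    cent = np.zeros((max_lab + 1, 3))
    cnt = np.bincount(labels.ravel(), minlength=max_lab + 1).astype(float)
    zz, yy, xx = np.nonzero(labels)
    lab_flat = labels[zz, yy, xx]
    np.add.at(cent, lab_flat, np.column_stack([(xx + 0.5) * sx, (yy + 0.5) * sy, (zz + 0.5) * sz]))
    cnt[cnt == 0] = 1.0
    cent /= cnt[:, None]
    proj = cent @ _AGE_DIR
    cells_proj = proj[1:] if max_lab else proj
    span = cells_proj.max() - cells_proj.min()
    g = (proj - cells_proj.min()) / (span if span > 0 else 1.0)

    w = 0.9 + params.age_gain * 0.5 * (g[pair_lo] + g[pair_hi])
    outer = (pair_lo == 0) | (pair_hi == 0)
    # the tissue surface wall is mature: brighter than local inner walls
    w[outer] = 0.9 + params.age_gain * g[np.maximum(pair_lo, pair_hi)[outer]] + 0.3
    # a new wall carries intensity_ratio x the *local* mature-wall level,
    # so ratio 1.0 really is the information-free limit
    w[planted_mask] *= params.intensity_ratio

    shape = labels.shape
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)
    flat_a = idx_a @ strides
    flat_b = idx_b @ strides
    # dimmest wall wins where voxels flank several walls: a thin new wall
    # keeps its own low signal right up to the junction with mature walls
    painted = np.full(shape[0] * shape[1] * shape[2], np.inf)
    w_face = w[inverse]
    np.minimum.at(painted, flat_a, w_face)
    np.minimum.at(painted, flat_b, w_face)

    # voxels flanking planted walls are never brightened by the fix-up pass
    planted_face = planted_mask[inverse]
    protected = np.zeros(len(painted), dtype=bool)
    protected[flat_a[planted_face]] = True
    protected[flat_b[planted_face]] = True

    eligible = (pair_lo != 0) & (pair_hi != 0) & (counts >= params.min_face_elements)
    bump_val = float(w.max()) + 0.2
    # relative SD of each facet's mean density under the configured noise
    sigma = params.noise_sd * np.sqrt(1.0 / np.maximum(counts, 1))
    prev_flagged: np.ndarray | None = None
    # in the information-free limit (ratio >= 1) planted walls are not
    # distinguishable even in principle; brightening would fake recovery
    n_passes = 120 if params.intensity_ratio < 1.0 else 0
    for _ in range(n_passes):
        dens_num = np.bincount(
            inverse,
            weights=face_area * 0.5 * (painted[flat_a] + painted[flat_b]),
            minlength=n_facets,
        )
        dens_den = np.bincount(inverse, weights=face_area, minlength=n_facets)
        dens = dens_num / dens_den
        cell_min = np.full(max_lab + 1, np.inf)
        np.minimum.at(cell_min, pair_lo[eligible], dens[eligible])
        np.minimum.at(cell_min, pair_hi[eligible], dens[eligible])
        # face count of (a tied representative of) each cell's weakest facet
        is_min_lo = eligible & (dens <= cell_min[pair_lo] + 1e-12)
        is_min_hi = eligible & (dens <= cell_min[pair_hi] + 1e-12)
        min_n = np.full(max_lab + 1, params.min_face_elements, dtype=np.int64)
        np.maximum.at(min_n, pair_lo[is_min_lo], counts[is_min_lo])
        np.maximum.at(min_n, pair_hi[is_min_hi], counts[is_min_hi])
        sig_min = params.noise_sd * np.sqrt(1.0 / min_n)
        guard_lo = params.guard_k * np.sqrt(sigma**2 + sig_min[pair_lo] ** 2)
        guard_hi = params.guard_k * np.sqrt(sigma**2 + sig_min[pair_hi] ** 2)
        flagged = (
            eligible
            & ~planted_mask
            & (dens <= cell_min[pair_lo] + guard_lo)
            & (dens <= cell_min[pair_hi] + guard_hi)
        )
        # an old wall dimmer than a cell's planted wall (possible through
        # junction contamination by a shallower division) would block the
        # planted call for that cell: brighten it as well
        cell_planted = np.full(max_lab + 1, np.inf)
        pm = planted_mask & eligible
        np.minimum.at(cell_planted, pair_lo[pm], dens[pm])
        np.minimum.at(cell_planted, pair_hi[pm], dens[pm])
        flagged |= (
            eligible
            & ~planted_mask
            & (
                (np.isfinite(cell_planted[pair_lo]) & (dens <= cell_planted[pair_lo] + guard_lo))
                | (np.isfinite(cell_planted[pair_hi]) & (dens <= cell_planted[pair_hi] + guard_hi))
            )
        )
        offenders = np.nonzero(flagged)[0]
        if len(offenders) == 0:
            break
        if prev_flagged is not None and np.array_equal(offenders, prev_flagged):
            # steady state: the remaining near-ties sit at saturated
            # brightness (the weakest wall of a fully-matured cell pair is
            # unavoidably mutually weakest); they are few and far above the
            # planted level, so they cost at most a little precision
            logger.info("%d saturated near-tie walls remain after brightening", len(offenders))
            break
        prev_flagged = offenders
        off_face = np.isin(inverse, offenders)
        ids = inverse[off_face]
        vox = np.concatenate([flat_a[off_face], flat_b[off_face]])
        vox_ids = np.concatenate([ids, ids])
        unprot = ~protected[vox]
        n_free = np.bincount(vox_ids[unprot], minlength=n_facets)
        # walls wedged entirely against planted walls get a moderate
        # multiplicative brightening of their junction voxels instead (this
        # raises the planted neighbours' density slightly, which keeps a
        # wide margin)
        wedged = n_free[vox_ids] == 0
        free = vox[unprot]
        painted[free] = np.maximum(painted[free], bump_val)
        painted[vox[wedged]] = np.minimum(painted[vox[wedged]] * 1.9, bump_val)
    else:
        logger.warning("old-wall brightening still changing after 120 passes")

    painted[~np.isfinite(painted)] = 0.0  # cell interiors and deep background
    values = painted.reshape(shape) * params.old_intensity
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd * params.old_intensity, shape)
    return np.clip(values, 0.0, None)


def evaluate_detection(facets, truth: pd.DataFrame) -> dict:
    """Compare called new walls against the generator's truth table.

    Returns recall, precision, counts, and the angular error (deg) between
    each matched facet's fitted plane normal and the planted normal.
    """
    called = {f.pair: f for f in facets if f.is_new_wall}
    truth_pairs = {
        (int(r.cell_a), int(r.cell_b)): np.array([r.normal_x, r.normal_y, r.normal_z])
        for r in truth.itertuples(index=False)
    }
    tp = set(called) & set(truth_pairs)
    recall = len(tp) / len(truth_pairs) if truth_pairs else float("nan")
    precision = len(tp) / len(called) if called else float("nan")
    errors = []
    for pair in sorted(tp):
        f = called[pair]
        if f.plane is None:
            continue
        c = abs(float(f.plane.normal @ truth_pairs[pair]))
        errors.append(float(np.degrees(np.arccos(np.clip(c, 0, 1)))))
    return {
        "n_truth": len(truth_pairs),
        "n_called": len(called),
        "n_matched": len(tp),
        "recall": recall,
        "precision": precision,
        "normal_errors_deg": np.array(errors),
    }


# ---------------------------------------------------------------------------
# clonal sectors


@dataclasses.dataclass
class SectorSimParams:
    """Planted clonal sectors: per-region counts and growth directions.

    ``directions`` maps region → (vertical angle deg, azimuth deg or
    "uniform"); sectors grow as chains of one landmark per cell with
    ``step_um`` spacing, direction jitter ``sd_direction`` and landmark
    jitter ``point_jitter_um``. Each apex gets a random pose (summit
    offset, axis tilt) so the alignment step is exercised.
    """

    n_per_region: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"AR": 15, "RC": 15, "RP": 15}
    )
    directions: Mapping[str, tuple[float, float | str]] = dataclasses.field(
        default_factory=lambda: {"AR": (90.0, "uniform"), "RC": (0.0, "uniform"), "RP": (25.0, "uniform")}
    )
    sd_direction: float = 8.0
    cells_range: tuple[int, int] = (4, 10)
    step_um: float = 4.0
    point_jitter_um: float = 1.0
    n_apices: int = 15
    max_axis_tilt: float = 15.0
    seed: int = 0


def generate_sectors(
    params: SectorSimParams,
) -> tuple[pd.DataFrame, dict[str, MeristemFrame], pd.DataFrame]:
    """Landmark table (raw apex coordinates), per-apex frames, truth table.

    Truth values are the measurements of the noise-free chains (before
    landmark jitter), together with the planted nominal angles.
    """
    from .sectors import _rotation_to_z, measure_sector

    rng = np.random.default_rng(params.seed)
    regions = {s.name: s for s in default_regions()}
    frames: dict[str, MeristemFrame] = {}
    for i in range(params.n_apices):
        summit = rng.uniform(40.0, 60.0, size=3)
        tilt = np.radians(rng.uniform(0.0, params.max_axis_tilt))
        az = rng.uniform(0, 2 * np.pi)
        axis = np.array(
            [np.sin(tilt) * np.cos(az), np.sin(tilt) * np.sin(az), np.cos(tilt)]
        )
        frames[f"apex{i:02d}"] = MeristemFrame(summit=summit, axis=axis)
    apex_ids = sorted(frames)

    lm_rows = []
    truth_rows = []
    k = 0
    for region_name, n_sec in params.n_per_region.items():
        spec = regions[region_name]
        alpha0, azimuth = params.directions[region_name]
        for _ in range(n_sec):
            apex_id = apex_ids[k % len(apex_ids)]
            sector_id = f"s{k:03d}"
            k += 1
            (d0, d1), (r0, r1) = spec.depth_range, spec.radius_range
            depth = rng.uniform(d0 + 2.0, d1 - 2.0)
            radius = rng.uniform(max(r0, 3.0), r1 - 1.0)
            theta = rng.uniform(0, 2 * np.pi)
            origin = np.array([radius * np.cos(theta), radius * np.sin(theta), -depth])
            rhat = np.array([np.cos(theta), np.sin(theta), 0.0])
            that = np.array([-np.sin(theta), np.cos(theta), 0.0])
            alpha = np.radians(alpha0 + rng.normal(0.0, params.sd_direction))
            psi = (
                rng.uniform(0, 2 * np.pi)
                if azimuth == "uniform"
                else np.radians(float(azimuth) + rng.normal(0.0, params.sd_direction))
            )
            u = (
                np.cos(alpha) * np.array([0.0, 0.0, 1.0])
                + np.sin(alpha) * (np.cos(psi) * rhat + np.sin(psi) * that)
            )
            n_c = int(rng.integers(params.cells_range[0], params.cells_range[1] + 1))
            clean = origin + np.arange(n_c)[:, None] * params.step_um * u
            noisy = clean + rng.normal(0.0, params.point_jitter_um, size=clean.shape)

            ref = measure_sector(clean, apex_id=apex_id, sector_id=sector_id)
            truth_rows.append(
                {
                    "apex_id": apex_id,
                    "sector_id": sector_id,
                    "region": region_name,
                    "planted_vertical_angle": float(np.degrees(abs(alpha)))
                    if np.degrees(abs(alpha)) <= 90
                    else 180 - float(np.degrees(abs(alpha))),
                    "true_vertical_angle": ref.vertical_angle,
                    "true_radial_angle": ref.sector_radial_angle,
                    "true_length": ref.length,
                    "n_cells": n_c,
                }
            )
            # place into the apex's raw coordinates (inverse of alignment)
            frame = frames[apex_id]
            R = _rotation_to_z(frame.axis)
            raw = noisy @ R + frame.summit  # (R^T p)^T rows = p @ R
            for p in raw:
                lm_rows.append(
                    {
                        "apex_id": apex_id,
                        "sector_id": sector_id,
                        "x_um": p[0],
                        "y_um": p[1],
                        "z_um": p[2],
                    }
                )
    landmarks = pd.DataFrame(lm_rows)
    truth = pd.DataFrame(truth_rows)
    return landmarks, frames, truth


# ---------------------------------------------------------------------------
# toy genome with replicate peaks


@dataclasses.dataclass
class GenomeSimParams:
    """Toy genome + replicate-peak forward model.

    True binding sites are placed inside gene-anchored zones (promoter /
    transcribed / downstream) with the given bias, re-emitted by each
    treatment replicate with positional jitter and a passing q-value, and
    accompanied by replicate-specific noise peaks and independent control
    peaks confined to a reserved gene-free tail of each chromosome (so the
    consensus rules have an exact known answer).
    """

    n_chroms: int = 2
    chrom_length: int = 100_000
    n_genes_per_chrom: int = 12
    transcript_len_range: tuple[int, int] = (1500, 3000)
    cds_margin_range: tuple[int, int] = (100, 300)
    n_sites: int = 50
    zone_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"promoter": 0.6, "transcribed": 0.2, "downstream": 0.2}
    )
    peak_width: int = 250
    replicate_jitter: int = 20
    q_range: tuple[float, float] = (3.0, 30.0)
    fold_range: tuple[float, float] = (2.0, 20.0)
    n_noise_per_replicate: int = 10
    n_control_per_replicate: int = 8
    tail_length: int = 20_000
    upstream: int = 3000
    downstream: int = 1500
    seed: int = 0


@dataclasses.dataclass
class GenomeSim:
    """In-memory result of :func:`generate_genome_and_peaks`."""

    genes: list[GeneModel]
    treatment: list[list[PeakCall]]
    controls: list[list[PeakCall]]
    truth: pd.DataFrame
    sequences: dict[str, str]
    params: GenomeSimParams

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write FASTA, GFF3, six narrowPeak files and the truth table."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        fasta = out / "genome.fa"
        with open(fasta, "w") as fh:
            for name in sorted(self.sequences):
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        paths["fasta"] = fasta
        gff = out / "genes.gff3"
        write_gff3(self.genes, gff)
        paths["gff3"] = gff
        for kind, reps in (("treatment", self.treatment), ("control", self.controls)):
            for i, peaks in enumerate(reps, start=1):
                p = out / f"{kind}_{i}.narrowPeak"
                write_narrowpeak(peaks, p)
                paths[f"{kind}_{i}"] = p
        tpath = out / "truth.csv"
        self.truth.to_csv(tpath, index=False)
        paths["truth"] = tpath
        return paths


_ZONE_CODE = {
    "promoter": ZONE_PROMOTER,
    "transcribed": ZONE_TRANSCRIBED,
    "downstream": ZONE_DOWNSTREAM,
}


def generate_genome_and_peaks(params: GenomeSimParams) -> GenomeSim:
    """Generate the toy genome, gene models, replicate peak sets and truth."""
    rng = np.random.default_rng(params.seed)
    L = params.chrom_length
    chroms = [f"chr{i + 1}" for i in range(params.n_chroms)]
    sequences = {
        c: "".join(rng.choice(list("ACGT"), size=L)) for c in chroms
    }

    genes: list[GeneModel] = []
    gene_region_end = L - params.tail_length - 500
    for c in chroms:
        cursor = params.upstream + 200
        gi = 0
        while True:
            tlen = int(rng.integers(*params.transcript_len_range))
            if cursor + tlen > gene_region_end or gi >= params.n_genes_per_chrom:
                break
            m5 = int(rng.integers(*params.cds_margin_range))
            m3 = int(rng.integers(*params.cds_margin_range))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"{c}_g{gi:03d}",
                    chrom=c,
                    strand=strand,
                    cds_start=cursor + m5,
                    cds_end=cursor + tlen - m3,
                    transcript_start=cursor,
                    transcript_end=cursor + tlen,
                )
            )
            gi += 1
            # keep neighbouring promoter/downstream windows from colliding
            cursor += tlen + params.upstream + params.downstream + int(rng.integers(200, 800))
        if gi < params.n_genes_per_chrom:
            logger.info("chrom %s holds %d genes (requested %d)", c, gi, params.n_genes_per_chrom)

    segments = _zone_segments(genes, params.upstream, params.downstream)
    # per-zone sampling pools: (chrom, start, end) segments
    pools: dict[int, list[tuple[str, int, int]]] = {z: [] for z in _ZONE_CODE.values()}
    for chrom, (bounds, codes) in sorted(segments.items()):
        for i, code in enumerate(codes):
            if code >= 0:
                pools[int(code)].append((chrom, int(bounds[i]), int(bounds[i + 1])))

    zone_names = sorted(params.zone_probs)
    zone_p = np.array([params.zone_probs[z] for z in zone_names], dtype=float)
    zone_p /= zone_p.sum()
    half = params.peak_width // 2
    min_sep = params.peak_width + 2 * params.replicate_jitter + 10

    centers: list[tuple[str, int, str]] = []
    attempts = 0
    while len(centers) < params.n_sites:
        attempts += 1
        if attempts > 200 * params.n_sites:
            raise ValueError("could not place the requested number of sites; genome too small")
        zone = zone_names[int(rng.choice(len(zone_names), p=zone_p))]
        segs = pools[_ZONE_CODE[zone]]
        lens = np.array([e - s for _, s, e in segs], dtype=float)
        si = int(rng.choice(len(segs), p=lens / lens.sum()))
        chrom, s, e = segs[si]
        pos = int(rng.integers(s, e))
        if pos - half < 0 or pos + half >= L:
            continue
        if any(c == chrom and abs(pos - p) < min_sep for c, p, _ in centers):
            continue
        centers.append((chrom, pos, zone))
    centers.sort()

    j = params.replicate_jitter
    treatment: list[list[PeakCall]] = [[] for _ in range(3)]
    for r in range(3):
        for i, (chrom, pos, zone) in enumerate(centers):
            js = int(rng.integers(-j, j + 1)) if j > 0 else 0
            je = int(rng.integers(-j, j + 1)) if j > 0 else 0
            start, end = pos - half + js, pos + half + je
            treatment[r].append(
                PeakCall(
                    chrom=chrom,
                    start=start,
                    end=end,
                    neg_log10_q=float(rng.uniform(*params.q_range)),
                    fold_enrichment=float(rng.uniform(*params.fold_range)),
                    summit_offset=(end - start) // 2,
                    replicate_id=f"rep{r + 1}",
                    name=f"t{r + 1}_site{i:03d}",
                )
            )

    # reserved tail slots keep noise and control peaks from ever forming a
    # three-replicate >=50 nt overlap or touching a true site
    stride = params.peak_width + 60
    slots = [
        (c, L - params.tail_length + k * stride)
        for c in chroms
        for k in range((params.tail_length - params.peak_width - 100) // stride)
    ]
    rng.shuffle(slots)
    need = 3 * (params.n_noise_per_replicate + params.n_control_per_replicate)
    if len(slots) < need:
        raise ValueError(f"only {len(slots)} reserved slots for {need} noise/control peaks")
    it = iter(slots)
    controls: list[list[PeakCall]] = [[] for _ in range(3)]
    for r in range(3):
        for i in range(params.n_noise_per_replicate):
            chrom, s = next(it)
            treatment[r].append(
                PeakCall(
                    chrom=chrom,
                    start=s,
                    end=s + params.peak_width,
                    neg_log10_q=float(rng.uniform(1.0, params.q_range[1])),
                    fold_enrichment=float(rng.uniform(1.0, 5.0)),
                    summit_offset=half,
                    replicate_id=f"rep{r + 1}",
                    name=f"t{r + 1}_noise{i:03d}",
                )
            )
        for i in range(params.n_control_per_replicate):
            chrom, s = next(it)
            controls[r].append(
                PeakCall(
                    chrom=chrom,
                    start=s,
                    end=s + params.peak_width,
                    neg_log10_q=float(rng.uniform(1.0, params.q_range[1])),
                    fold_enrichment=float(rng.uniform(1.0, 5.0)),
                    summit_offset=half,
                    replicate_id=f"ctrl{r + 1}",
                    name=f"c{r + 1}_peak{i:03d}",
                )
            )
    for r in range(3):
        treatment[r].sort(key=lambda p: (p.chrom, p.start))
        controls[r].sort(key=lambda p: (p.chrom, p.start))

    truth = pd.DataFrame(
        [
            {
                "chrom": chrom,
                "start": pos - half,
                "end": pos + half,
                "center": pos,
                "zone": zone,
            }
            for chrom, pos, zone in centers
        ]
    )
    return GenomeSim(
        genes=genes,
        treatment=treatment,
        controls=controls,
        truth=truth,
        sequences=sequences,
        params=params,
    )
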