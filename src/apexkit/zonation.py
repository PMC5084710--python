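"""Meristem zonation windows and region-wise angle statistics.

Three standard regions, in depth-below-summit × radius-from-axis windows
(μm): the apical region (AR, depth 0-30, radius 0-40) covering the central
and peripheral zones, the rib-meristem core (RC, depth 30-60, radius 0-40)
where the pith originates, and the rib-meristem periphery (RP, depth 30-60,
radius 40-50). Windows are half-open ``[min, max)`` so the shared 30 μm and
40 μm boundaries belong unambiguously to the deeper / outer region.

Distribution comparisons use the two-sided Mann-Whitney U test with an
exact, tie-aware enumeration for small samples and the tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import MeristemFrame, depth_and_radius

__all__ = [
    "RegionSpec",
    "AngleSample",
    "default_regions",
    "classify_point",
    "classify_facet",
    "mann_whitney_u",
    "compare_angles",
    "summarize_by_region",
    "NONE_REGION",
]

logger = logging.getLogger(__name__)

NONE_REGION = "NONE"

#: Largest number of group assignments enumerated by the exact path.
_EXACT_MAX_COMBOS = 5_000_000
#: Exact enumeration is used when min(n1, n2) <= this.
EXACT_MAX_MIN_N = 8


@dataclasses.dataclass(frozen=True)
class RegionSpec:
    """A named depth × radius window (μm), half-open on both ranges."""

    name: str
    depth_range: tuple[float, float]
    radius_range: tuple[float, float]

    def __post_init__(self):
        for lo, hi in (self.depth_range, self.radius_range):
            if not (lo < hi):
                raise ValueError(f"degenerate range [{lo}, {hi}) in region {self.name}")

    def contains(self, depth: float, radius: float) -> bool:
        (d0, d1), (r0, r1) = self.depth_range, self.radius_range
        return d0 <= depth < d1 and r0 <= radius < r1


@dataclasses.dataclass(frozen=True)
class AngleSample:
    """Angle values (deg) for one region × group × metric combination."""

    region: str
    group: str
    metric: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        v = v[np.isfinite(v)]
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.values)


def default_regions() -> list[RegionSpec]:
    """AR / RC / RP windows (μm): the standard zonation of the upper stem."""
    return [
        RegionSpec("AR", (0.0, 30.0), (0.0, 40.0)),
        RegionSpec("RC", (30.0, 60.0), (0.0, 40.0)),
        RegionSpec("RP", (30.0, 60.0), (40.0, 50.0)),
    ]


def classify_point(depth: float, radius: float, regions: Sequence[RegionSpec]) -> str:
    """First region whose window contains (depth, radius); NONE otherwise."""
    for spec in regions:
        if spec.contains(depth, radius):
            return spec.name
    return NONE_REGION


_warned_overlap = False


def classify_facet(facet, frame: MeristemFrame, regions: Sequence[RegionSpec]) -> str:
    """Region of a facet's centroid (first match wins for overlapping specs)."""
    global _warned_overlap
    depth, radius = depth_and_radius(facet.centroid, frame)
    matches = [s.name for s in regions if s.contains(depth, radius)]
    if len(matches) > 1 and not _warned_overlap:
        logger.warning("overlapping region specs %s; first match wins", matches)
        _warned_overlap = True
    return matches[0] if matches else NONE_REGION


def _mw_u1(x: np.ndarray, y: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([x, y]))
    n1 = len(x)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _mw_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by enumerating all group assignments.

    Works with ties: pooled midranks are doubled to integers so U values
    and comparisons are exact. p = P(|U - n1 n2 / 2| >= |u_obs - n1 n2 / 2|)
    under random assignment (the permutation distribution is symmetric
    about n1 n2 / 2).
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2.0 * sps.rankdata(pooled)).astype(np.int64)  # midranks*2: exact ints
    u_obs2 = int(ranks2[:n1].sum() - n1 * (n1 + 1))  # 2*U1
    # enumerate the smaller side for speed; U distribution symmetry makes
    # |U1 - mu| == |U2 - mu| so either side gives the same two-sided count
    k = min(n1, n2)
    if k == n2:
        ranks_for = ranks2
        k_obs2 = int(ranks2[n1:].sum() - n2 * (n2 + 1))
        kk = n2
    else:
        ranks_for = ranks2
        k_obs2 = u_obs2
        kk = n1
    total = math.comb(n1 + n2, kk)
    if total > _EXACT_MAX_COMBOS:
        raise ValueError(
            f"exact enumeration of {total} assignments exceeds the cap; use the approximate path"
        )
    mu2 = n1 * n2  # 2 * (n1 n2 / 2)
    dev_obs = abs(k_obs2 - mu2)
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n1 + n2), kk)),
        dtype=np.int64,
        count=total * kk,
    ).reshape(total, kk)
    u2 = ranks_for[combos].sum(axis=1) - kk * (kk + 1)
    count = int(np.count_nonzero(np.abs(u2 - mu2) >= dev_obs))
    u1 = u_obs2 / 2.0
    return u1, count / total


def _mw_approx(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected normal approximation with continuity correction."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    u1 = _mw_u1(x, y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u1, 1.0  # all values identical
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return u1, p


def mann_whitney_u(
    sample_1: Sequence[float] | np.ndarray,
    sample_2: Sequence[float] | np.ndarray,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample_1, p).

    Exact tie-aware enumeration when ``min(n1, n2) <= 8`` (and the number of
    assignments is tractable); tie-corrected normal approximation with
    continuity correction otherwise.
    """
    x = np.asarray(sample_1, dtype=float)
    y = np.asarray(sample_2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("Mann-Whitney requires both samples non-empty")
    if min(len(x), len(y)) <= EXACT_MAX_MIN_N:
        try:
            return _mw_exact(x, y)
        except ValueError:
            pass
    return _mw_approx(x, y)


def compare_angles(sample_1: AngleSample, sample_2: AngleSample) -> tuple[float, float]:
    """Mann-Whitney comparison of two angle samples; returns (U, p)."""
    return mann_whitney_u(sample_1.values, sample_2.values)


def _hazen_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """Median and quartiles by the Hazen rule (linear interpolation,
    h = n p + 1/2), the convention used throughout the package."""
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="hazen")
    return float(q1), float(med), float(q3)


def summarize_by_region(
    facets: Iterable,
    frame: MeristemFrame,
    regions: Sequence[RegionSpec] | None = None,
    group: str = "all",
    metrics: Sequence[str] = ("angle_to_axis", "radial_angle"),
    new_walls_only: bool = True,
) -> pd.DataFrame:
    """Boxplot-style summary per region × metric for one group of facets.

    Reports n, median, quartiles (Hazen rule), whisker bounds (most extreme
    data within 1.5×IQR of the quartiles) and the outliers beyond them.
    Only new walls are included by default; NaN (undefined) angles are
    dropped per metric.
    """
    if regions is None:
        regions = default_regions()
    rows = []
    by_region: dict[str, list] = {s.name: [] for s in regions}
    for f in facets:
        if new_walls_only and not f.is_new_wall:
            continue
        name = classify_facet(f, frame, regions)
        if name in by_region:
            by_region[name].append(f)
    for spec in regions:
        for metric in metrics:
            vals = np.array(
                [getattr(f, metric) for f in by_region[spec.name]], dtype=float
            )
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                rows.append(
                    {
                        "group": group,
                        "region": spec.name,
                        "metric": metric,
                        "n": 0,
                        "median": np.nan,
                        "q1": np.nan,
                        "q3": np.nan,
                        "whisker_lo": np.nan,
                        "whisker_hi": np.nan,
                        "outliers": "",
                    }
                )
                continue
            q1, med, q3 = _hazen_quartiles(vals)
            iqr = q3 - q1
            lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = vals[(vals >= lo_lim) & (vals <= hi_lim)]
            out = vals[(vals < lo_lim) | (vals > hi_lim)]
            rows.append(
                {
                    "group": group,
                    "region": spec.name,
                    "metric": metric,
                    "n": len(vals),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_lo": float(inside.min()),
                    "whisker_hi": float(inside.max()),
                    "outliers": ";".join(f"{v:g}" for v in sorted(out)),
                }
            )
    return pd.DataFrame(rows)


def angle_samples(
    facets: Iterable,
    frame: MeristemFrame,
    regions: Sequence[RegionSpec] | None = None,
    group: str = "all",
    metric: str = "angle_to_axis",
    new_walls_only: bool = True,
) -> dict[str, AngleSample]:
    """Collect per-region angle samples for one group (new walls by default)."""
    if regions is None:
        regions = default_regions()
    vals: dict[str, list[float]] = {s.name: [] for s in regions}
    for f in facets:
        if new_walls_only and not f.is_new_wall:
            continue
        name = classify_facet(f, frame, regions)
        if name in vals:
            vals[name].append(getattr(f, metric))
    return {
        name: AngleSample(region=name, group=group, metric=metric, values=np.array(v))
        for name, v in vals.items()
    }
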