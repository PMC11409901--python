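"""Per-cluster morphometrics and per-image summaries.

Cluster "radius" is the 3D radius of gyration — the root-mean-square
distance of a cluster's localizations to their centroid.  It is
deterministic and far less outlier-sensitive than the maximum distance (a
``definition="max"`` switch exposes the latter for sensitivity checks).
Reference values: two points ``d`` apart have gyration radius ``d/2``; a
uniform ball of radius R has gyration radius ``R*sqrt(3/5)``; an isotropic
Gaussian with per-axis sd ``s`` has gyration radius ``s*sqrt(3)``.

Densities come in three flavours, all emitted side by side:

* ``density_raw`` — localizations per nm^3 of the gyration sphere,
  ``n / ((4/3) pi r^3)``;
* ``density_platform`` — ``1000 * density_raw``, the platform's
  convenience scaling (always exactly 1000x);
* ``density_2d`` — localizations per nm^2 of the projected gyration disc,
  ``n / (pi r^2)``.

ROI volume normalizes localization counts across images; the default is
the convex hull of the localization cloud (tightest deterministic proxy
for the imaged structure), with axis-aligned bounding box and
user-supplied bounds as alternatives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .dbscan_cluster import ClusterAssignment
from .loc_io import LocalizationTable

__all__ = [
    "ClusterMetricsRecord",
    "ImageSummary",
    "cluster_radius",
    "cluster_density",
    "summarize_clusters",
    "roi_volume",
    "image_summary",
]

PLATFORM_DENSITY_SCALE = 1000.0


@dataclass
class ClusterMetricsRecord:
    """Morphometrics of one cluster."""

    cluster_id: int
    n_localizations: int
    centroid: tuple[float, float, float]
    radius: float  # nm
    volume: float  # nm^3 of the gyration sphere
    density_raw: float  # localizations / nm^3
    density_platform: float  # 1000 x density_raw
    density_2d: float  # localizations / nm^2 (projected disc)


@dataclass
class ImageSummary:
    """Aggregated cluster metrics of one image.

    Means over clusters ignore clusters with undefined density (coincident
    points); ``degenerate`` marks an image with zero localizations.
    """

    image_id: str
    n_clusters: int
    mean_radius: float | None
    mean_density_platform: float | None
    mean_locs_per_cluster: float | None
    pct_locs_clustered: float
    n_localizations_total: int
    roi_volume: float | None
    locs_per_roi_volume: float | None
    degenerate: bool = False


def cluster_radius(coords: np.ndarray, definition: str = "gyration") -> float:
    """Cluster radius in nm from member coordinates (n, 3).

    ``definition="gyration"`` (default): sqrt of the mean squared distance
    to the centroid; ``"max"``: maximum distance to the centroid.
    Singletons have radius 0 by convention.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    if len(coords) == 0:
        raise ValueError("cluster must have at least one member")
    sq = np.sum((coords - coords.mean(axis=0)) ** 2, axis=1)
    if definition == "gyration":
        return float(np.sqrt(sq.mean()))
    if definition == "max":
        return float(np.sqrt(sq.max()))
    raise ValueError("definition must be 'gyration' or 'max'")


def cluster_density(n: int, radius: float) -> tuple[float, float, float]:
    """(density_raw, density_platform, density_2d) from size and radius.

    A zero radius with n >= 2 (coincident points) yields infinite
    densities, flagged with a warning; callers exclude such clusters from
    means.
    """
    if n < 2:
        raise ValueError("density requires at least 2 localizations")
    if radius == 0:
        warnings.warn(
            "coincident cluster members: density undefined (infinite)",
            stacklevel=2,
        )
        return math.inf, math.inf, math.inf
    raw = n / ((4.0 / 3.0) * math.pi * radius**3)
    return raw, PLATFORM_DENSITY_SCALE * raw, n / (math.pi * radius**2)


def summarize_clusters(
    table: LocalizationTable,
    assignment: ClusterAssignment,
    radius_definition: str = "gyration",
) -> pd.DataFrame:
    """One metrics row per non-noise cluster.

    The sum of ``n_localizations`` over rows equals the number of non-noise
    labels in the assignment (conservation).
    """
    if len(assignment) != len(table):
        raise ValueError(
            f"assignment length {len(assignment)} != table length {len(table)}"
        )
    coords = table.coords
    rows = []
    for cid in range(assignment.n_clusters):
        members = coords[assignment.labels == cid]
        n = len(members)
        centroid = members.mean(axis=0)
        radius = cluster_radius(members, definition=radius_definition)
        if n >= 2:
            raw, platform, density_2d = cluster_density(n, radius)
        else:
            raw = platform = density_2d = math.nan
        rows.append(
            {
                "cluster_id": cid,
                "n_localizations": n,
                "centroid_x": centroid[0],
                "centroid_y": centroid[1],
                "centroid_z": centroid[2],
                "radius_nm": radius,
                "volume_nm3": (4.0 / 3.0) * math.pi * radius**3,
                "density_raw": raw,
                "density_platform": platform,
                "density_2d": density_2d,
            }
        )
    columns = [
        "cluster_id", "n_localizations", "centroid_x", "centroid_y",
        "centroid_z", "radius_nm", "volume_nm3", "density_raw",
        "density_platform", "density_2d",
    ]
    return pd.DataFrame(rows, columns=columns)


def roi_volume(
    table: LocalizationTable,
    method: str = "convex_hull",
    bounds: tuple | None = None,
) -> float:
    """Volume (nm^3) of the image's region of interest.

    ``convex_hull`` (default) falls back to the bounding box, with a
    warning, when the cloud has fewer than 4 points or is degenerate
    (coplanar/collinear).  ``user_bounds`` uses explicit
    ``((xmin, xmax), (ymin, ymax), (zmin, zmax))`` bounds (argument or
    ``table.roi_bounds``).
    """
    if method == "user_bounds":
        box = bounds or table.roi_bounds
        if box is None:
            raise ValueError("user_bounds requires explicit bounds or table.roi_bounds")
        extents = [hi - lo for lo, hi in box]
        if any(e <= 0 for e in extents):
            raise ValueError(f"degenerate user bounds (non-positive extent): {box}")
        return float(np.prod(extents))

    coords = table.coords
    if len(coords) == 0:
        raise ValueError("cannot compute an ROI volume for an empty table")

    if method == "convex_hull":
        if len(coords) >= 4:
            try:
                return float(ConvexHull(coords).volume)
            except QhullError:
                pass
        warnings.warn(
            f"{table.image_id}: degenerate geometry for convex hull; "
            "falling back to bounding box",
            stacklevel=2,
        )
        method = "bounding_box"

    if method == "bounding_box":
        extents = coords.max(axis=0) - coords.min(axis=0)
        volume = float(np.prod(extents))
        if volume <= 0:
            raise ValueError(
                f"{table.image_id}: zero-extent bounding box; ROI volume undefined"
            )
        return volume

    raise ValueError(
        "method must be 'convex_hull', 'bounding_box' or 'user_bounds'"
    )


def image_summary(
    table: LocalizationTable,
    assignment: ClusterAssignment,
    roi_method: str = "convex_hull",
    bounds: tuple | None = None,
    radius_definition: str = "gyration",
) -> ImageSummary:
    """Aggregate per-cluster records into per-image means and totals."""
    n_total = len(table)
    if n_total == 0:
        return ImageSummary(
            image_id=table.image_id,
            n_clusters=0,
            mean_radius=None,
            mean_density_platform=None,
            mean_locs_per_cluster=None,
            pct_locs_clustered=0.0,
            n_localizations_total=0,
            roi_volume=None,
            locs_per_roi_volume=None,
            degenerate=True,
        )
    records = summarize_clusters(table, assignment, radius_definition)
    n_clustered = int(assignment.clustered_mask.sum())
    volume = roi_volume(table, method=roi_method, bounds=bounds)

    if len(records):
        mean_radius = float(records["radius_nm"].mean())
        mean_locs = float(records["n_localizations"].mean())
        dens = records["density_platform"].to_numpy(dtype=float)
        finite = np.isfinite(dens)
        if not finite.all():
            warnings.warn(
                f"{table.image_id}: {int((~finite).sum())} cluster(s) with "
                "undefined density excluded from the image mean",
                stacklevel=2,
            )
        mean_density = float(dens[finite].mean()) if finite.any() else None
    else:
        mean_radius = mean_locs = mean_density = None

    return ImageSummary(
        image_id=table.image_id,
        n_clusters=int(len(records)),
        mean_radius=mean_radius,
        mean_density_platform=mean_density,
        mean_locs_per_cluster=mean_locs,
        pct_locs_clustered=100.0 * n_clustered / n_total,
        n_localizations_total=n_total,
        roi_volume=volume,
        locs_per_roi_volume=n_total / volume,
    )
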