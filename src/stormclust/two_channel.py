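"""Two-channel ratio analysis.

In two-colour dSTORM of skin innervation one channel images a neuronal
marker (PGP9.5, labelling nerve fibres) and the other alpha-synuclein
(total or Ser129-phosphorylated).  Per image, this module reports the
ratio of the volume occupied by each channel and the ratio of localization
counts, with the marker channel in the numerator.  A falling
marker-to-aSyn count ratio indicates less preserved nerve tissue where
aSyn is enriched.

"Volume covered" by a channel is, by default, that channel's convex-hull
ROI volume; a ``voxel_occupancy`` alternative (number of occupied voxels x
voxel volume, voxel size shared with FOCAL) is provided because convex
hulls overestimate sparse, branched structures.  A volume *difference*
column is emitted alongside the ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .cluster_metrics import roi_volume
from .focal_cluster import voxelize
from .loc_io import CohortManifest, LocalizationTable

__all__ = ["ChannelRatioRecord", "channel_ratios", "cohort_ratio_table"]

logger = logging.getLogger(__name__)

_VOLUME_METHODS = ("convex_hull", "bounding_box", "voxel_occupancy")


@dataclass
class ChannelRatioRecord:
    """Per-image two-channel comparison (channel A / channel B).

    Undefined ratios (empty denominator channel) are NaN and listed in
    ``flags`` — never silently dropped.
    """

    image_id: str
    channel_A: str
    channel_B: str
    volume_A: float
    volume_B: float
    volume_ratio: float
    volume_diff: float
    count_A: int
    count_B: int
    count_ratio: float
    flags: list[str] = field(default_factory=list)


def _channel_volume(
    table: LocalizationTable, method: str, voxel_size: float
) -> float:
    if method == "voxel_occupancy":
        if len(table) == 0:
            return 0.0
        grid = voxelize(table, voxel_size)
        return len(grid.members) * voxel_size**3
    return roi_volume(table, method=method)


def channel_ratios(
    table_A: LocalizationTable,
    table_B: LocalizationTable,
    roi_method: str = "convex_hull",
    voxel_size: float = 50.0,
) -> ChannelRatioRecord:
    """Volume and localization-count ratios of two registered channels.

    Both tables must come from the same image (same ``image_id`` and
    coordinate frame).
    """
    if table_A.image_id != table_B.image_id:
        raise ValueError(
            f"channel tables belong to different images: "
            f"{table_A.image_id!r} vs {table_B.image_id!r}"
        )
    if roi_method not in _VOLUME_METHODS:
        raise ValueError(f"roi_method must be one of {_VOLUME_METHODS}")
    flags: list[str] = []
    channel = lambda t: t.data["channel"].iloc[0] if len(t) else "default"

    count_A, count_B = len(table_A), len(table_B)
    if count_B == 0:
        flags.append("count_ratio_undefined_empty_B")
        count_ratio = math.nan
        volume_A = _channel_volume(table_A, roi_method, voxel_size) if count_A else 0.0
        return ChannelRatioRecord(
            image_id=table_A.image_id,
            channel_A=channel(table_A),
            channel_B=channel(table_B),
            volume_A=volume_A,
            volume_B=0.0,
            volume_ratio=math.nan,
            volume_diff=volume_A,
            count_A=count_A,
            count_B=0,
            count_ratio=count_ratio,
            flags=flags + ["volume_ratio_undefined_empty_B"],
        )
    count_ratio = count_A / count_B
    volume_A = _channel_volume(table_A, roi_method, voxel_size) if count_A else 0.0
    volume_B = _channel_volume(table_B, roi_method, voxel_size)
    if count_A == 0:
        flags.append("empty_channel_A")
    if volume_B > 0:
        volume_ratio = volume_A / volume_B
    else:
        volume_ratio = math.nan
        flags.append("volume_ratio_undefined_zero_B")
    return ChannelRatioRecord(
        image_id=table_A.image_id,
        channel_A=channel(table_A),
        channel_B=channel(table_B),
        volume_A=volume_A,
        volume_B=volume_B,
        volume_ratio=volume_ratio,
        volume_diff=volume_A - volume_B,
        count_A=count_A,
        count_B=count_B,
        count_ratio=count_ratio,
        flags=flags,
    )


def cohort_ratio_table(
    manifest: CohortManifest,
    tables: dict[str, dict[str, LocalizationTable]],
    channel_A: str = "PGP9.5",
    channel_B: str = "aSyn",
    roi_method: str = "convex_hull",
    voxel_size: float = 50.0,
) -> pd.DataFrame:
    """Per-image ratio records for a cohort, annotated by subject and group.

    ``tables`` maps ``image_id -> channel -> LocalizationTable``.  Images
    missing either channel are excluded with a logged warning; having no
    complete image at all is an error.
    """
    if not manifest.image_ids:
        raise ValueError("empty manifest")
    rows = []
    for image_id in manifest.image_ids:
        per_channel = tables.get(image_id, {})
        if channel_A not in per_channel or channel_B not in per_channel:
            logger.warning(
                "image %s missing channel %s; excluded from ratio table",
                image_id,
                channel_A if channel_A not in per_channel else channel_B,
            )
            continue
        rec = channel_ratios(
            per_channel[channel_A],
            per_channel[channel_B],
            roi_method=roi_method,
            voxel_size=voxel_size,
        )
        subject = manifest.subject_of(image_id)
        rows.append(
            {
                "image_id": image_id,
                "subject_id": subject,
                "group": manifest.group_of_subject(subject),
                "channel_A": channel_A,
                "channel_B": channel_B,
                "volume_A": rec.volume_A,
                "volume_B": rec.volume_B,
                "volume_ratio": rec.volume_ratio,
                "volume_diff": rec.volume_diff,
                "count_A": rec.count_A,
                "count_B": rec.count_B,
                "count_ratio": rec.count_ratio,
                "flags": ";".join(rec.flags),
            }
        )
    if not rows:
        raise ValueError("no image has both channels; cannot build ratio table")
    return pd.DataFrame(rows)
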