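"""Ground-truth SMLM localization simulator.

Emulates the statistical structure of a dSTORM image of labelled protein
aggregates so that every stage of the toolkit is testable without
microscope data:

* **nano-clusters** — isotropic 3D Gaussian clouds (per-axis sd
  ``cluster_sigma``; gyration radius ``cluster_sigma * sqrt(3)``) around
  centres placed uniformly in the ROI with a minimum separation of
  ``min_separation_factor * cluster_sigma`` enforced by rejection
  sampling; member counts are Poisson;
* **background** — spatially uniform localizations at a fixed density
  (localizations / nm^3), Poisson in number;
* **photon counts** — lognormal; inside clusters the count is multiplied
  by ``cluster_pc_multiplier`` attenuated radially (full factor at the
  cluster centre, decaying to 1 at the periphery with a Gaussian profile
  of the cluster's own width).  Densely labelled aggregate cores emit
  brighter events than their loosely decorated fringes, which is exactly
  the structure a voxel-average photon-count gate exploits: raising the
  gate peels off the dim periphery first.  ``cluster_pc_profile="flat"``
  applies the multiplier uniformly instead;
* **precision coupling** — ``sigma_x = sigma_y = s0 / sqrt(PC)`` (the
  standard photon-limited localization-error scaling) and ``sigma_z = 2 *
  sigma_x`` (axial precision is ~2x worse in biplane detection).

Defaults describe one image of the emulated study: a 10 x 10 µm ROI, a
few-hundred-nm axial range, ~60 clusters of ~200 localizations with a
69 nm gyration radius, PC median 1,500 photons (x2.5 in clusters) so that
lateral precision lands in the 10–20 nm range.  Every entry point is
deterministic given a seed.

What the simulator does *not* emulate: fluorophore blinking/re-blinking
kinetics, drift, fibril-like anisotropic aggregate shapes, or detector
noise; see the package documentation for the implications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .loc_io import CohortManifest, LocalizationTable

__all__ = [
    "SimulationConfig",
    "CohortConfig",
    "GroundTruth",
    "CohortData",
    "SimulationError",
    "simulate_image",
    "simulate_cohort",
    "simulate_two_channel",
]


class SimulationError(RuntimeError):
    """Raised when a simulation is geometrically infeasible."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dSTORM image.

    Attributes
    ----------
    roi_extent:
        (x, y, z) ROI edge lengths in nm.
    n_clusters:
        Number of planted nano-clusters.
    locs_per_cluster:
        Mean localizations per cluster (Poisson).
    cluster_sigma:
        Per-axis Gaussian spread in nm; gyration radius = sigma * sqrt(3).
    background_density:
        Uniform background, localizations / nm^3.
    pc_log_mean, pc_log_sd:
        Lognormal photon-count parameters (log photons).
    cluster_pc_multiplier:
        Photon-count factor at a cluster's centre.
    cluster_pc_profile:
        ``"radial"`` (default): the multiplier decays with distance r from
        the cluster centre as ``multiplier ** exp(-r^2 / (2 sigma^2))``,
        reaching 1 far outside the core; ``"flat"``: applied uniformly to
        every cluster member.
    precision_s0:
        Precision scale in nm * sqrt(photons): sigma_x = s0 / sqrt(PC).
    axial_precision_factor:
        sigma_z / sigma_x (default 2).
    min_separation_factor:
        Minimum centre separation in units of cluster_sigma (default 4).
    """

    roi_extent: tuple[float, float, float] = (10_000.0, 10_000.0, 600.0)
    n_clusters: int = 60
    locs_per_cluster: float = 200.0
    cluster_sigma: float = 40.0
    background_density: float = 5e-7
    pc_log_mean: float = math.log(1500.0)
    pc_log_sd: float = 0.5
    cluster_pc_multiplier: float = 6.0
    cluster_pc_profile: str = "radial"
    precision_s0: float = 700.0
    axial_precision_factor: float = 2.0
    min_separation_factor: float = 4.0
    channel: str = "default"

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.roi_extent):
            raise ValueError("roi_extent must be positive per axis")
        if self.n_clusters < 0 or self.locs_per_cluster < 0:
            raise ValueError("counts must be >= 0")
        if self.cluster_sigma <= 0 or self.precision_s0 <= 0:
            raise ValueError("cluster_sigma and precision_s0 must be > 0")
        if self.background_density < 0:
            raise ValueError("background_density must be >= 0")
        if self.cluster_pc_multiplier < 1:
            raise ValueError("cluster_pc_multiplier must be >= 1")
        if self.cluster_pc_profile not in ("radial", "flat"):
            raise ValueError("cluster_pc_profile must be 'radial' or 'flat'")


@dataclass
class GroundTruth:
    """True generative labels of a simulated image.

    ``labels[i]`` is the planted cluster id of localization ``i`` or -1
    for background; ``centers`` are the true cluster centres (k, 3) and
    ``cluster_sigma`` the true per-axis spread.
    """

    labels: np.ndarray
    centers: np.ndarray
    cluster_sigma: float

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def _place_centers(
    config: SimulationConfig,
    rng: np.random.Generator,
    preset: np.ndarray | None = None,
    max_attempts_per_cluster: int = 1000,
) -> np.ndarray:
    """Uniform centres with rejection-enforced minimum separation."""
    extent = np.asarray(config.roi_extent)
    min_sep = config.min_separation_factor * config.cluster_sigma
    centers: list[np.ndarray] = [] if preset is None else [c for c in preset]
    n_new = config.n_clusters - len(centers)
    attempts = 0
    budget = max_attempts_per_cluster * max(n_new, 1)
    while len(centers) < config.n_clusters:
        candidate = rng.uniform(0, extent)
        ok = all(np.linalg.norm(candidate - c) >= min_sep for c in centers)
        if ok:
            centers.append(candidate)
        attempts += 1
        if attempts > budget:
            raise SimulationError(
                f"could not place {config.n_clusters} cluster centres at "
                f"separation {min_sep:.0f} nm in ROI {tuple(extent)} after "
                f"{attempts} attempts"
            )
    return np.asarray(centers).reshape(config.n_clusters, 3)


def simulate_image(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence | None = None,
    image_id: str = "sim-000",
    preset_centers: np.ndarray | None = None,
) -> tuple[LocalizationTable, GroundTruth]:
    """Simulate one image; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    extent = np.asarray(config.roi_extent)

    centers = _place_centers(config, rng, preset=preset_centers)
    coords_parts: list[np.ndarray] = []
    labels_parts: list[np.ndarray] = []
    in_cluster_parts: list[np.ndarray] = []

    for cid, center in enumerate(centers):
        n = rng.poisson(config.locs_per_cluster)
        pts = rng.normal(loc=center, scale=config.cluster_sigma, size=(n, 3))
        coords_parts.append(pts)
        labels_parts.append(np.full(n, cid, dtype=np.int64))
        in_cluster_parts.append(np.ones(n, dtype=bool))

    volume = float(np.prod(extent))
    n_bg = rng.poisson(config.background_density * volume)
    coords_parts.append(rng.uniform(0, extent, size=(n_bg, 3)))
    labels_parts.append(np.full(n_bg, -1, dtype=np.int64))
    in_cluster_parts.append(np.zeros(n_bg, dtype=bool))

    coords = np.vstack(coords_parts) if coords_parts else np.empty((0, 3))
    labels = np.concatenate(labels_parts)
    in_cluster = np.concatenate(in_cluster_parts)
    n = len(coords)

    pc = rng.lognormal(mean=config.pc_log_mean, sigma=config.pc_log_sd, size=n)
    if in_cluster.any():
        member_r = np.linalg.norm(
            coords[in_cluster] - centers[labels[in_cluster]], axis=1
        )
        if config.cluster_pc_profile == "radial":
            # full multiplier at the core, ~1 beyond a few sigma
            attenuation = np.exp(-(member_r**2) / (2 * config.cluster_sigma**2))
            pc[in_cluster] *= config.cluster_pc_multiplier**attenuation
        else:
            pc[in_cluster] *= config.cluster_pc_multiplier
    sigma_x = config.precision_s0 / np.sqrt(pc)
    frame = rng.integers(0, 6000, size=n)

    data = pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "photon_count": pc,
            "sigma_x": sigma_x,
            "sigma_y": sigma_x,
            "sigma_z": config.axial_precision_factor * sigma_x,
            "frame": frame,
            "channel": config.channel,
        }
    )
    table = LocalizationTable(
        data=data,
        image_id=image_id,
        roi_bounds=tuple((0.0, float(e)) for e in extent),
    )
    return table, GroundTruth(
        labels=labels, centers=centers, cluster_sigma=config.cluster_sigma
    )


@dataclass(frozen=True)
class CohortConfig:
    """Two-group hierarchical cohort design.

    Subject-level heterogeneity is a lognormal random multiplier (sd
    ``subject_sd`` on the log scale) on the expected cluster count; the
    realized per-image cluster count is Poisson around the subject mean.
    ``group_effects`` maps a group label to multipliers on selected
    ``SimulationConfig`` fields (``n_clusters``, ``cluster_sigma``,
    ``locs_per_cluster``, ``background_density``); groups without an entry
    use the base configuration (no effect).
    """

    base: SimulationConfig = field(default_factory=SimulationConfig)
    groups: tuple[str, str] = ("A", "B")
    n_subjects_per_group: int = 6
    images_per_subject: int = 10
    subject_sd: float = 0.15
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1 or self.images_per_subject < 1:
            raise ValueError("need >= 1 subject per group and >= 1 image per subject")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        unknown = {
            k for eff in self.group_effects.values() for k in eff
        } - {"n_clusters", "cluster_sigma", "locs_per_cluster", "background_density"}
        if unknown:
            raise ValueError(f"unknown effect field(s): {sorted(unknown)}")


@dataclass
class CohortData:
    """Simulated cohort: tables, manifest, and per-image ground truth."""

    tables: dict[str, LocalizationTable]
    manifest: CohortManifest
    ground_truth: dict[str, GroundTruth]


def simulate_cohort(config: CohortConfig, seed: int) -> CohortData:
    """Simulate a two-group cohort; deterministic for a fixed seed."""
    root = np.random.SeedSequence(seed)
    subject_ss, image_ss = root.spawn(2)
    subject_rng = np.random.default_rng(subject_ss)

    tables: dict[str, LocalizationTable] = {}
    ground_truth: dict[str, GroundTruth] = {}
    manifest_rows = []
    image_seeds = iter(
        image_ss.spawn(2 * config.n_subjects_per_group * config.images_per_subject)
    )

    for group in config.groups:
        effects = config.group_effects.get(group, {})
        for s in range(config.n_subjects_per_group):
            subject_id = f"{group}{s + 1:02d}"
            subj_mult = subject_rng.lognormal(mean=0.0, sigma=config.subject_sd)
            for j in range(config.images_per_subject):
                image_id = f"{subject_id}-img{j + 1:02d}"
                ss = next(image_seeds)
                rng = np.random.default_rng(ss)
                mean_clusters = (
                    config.base.n_clusters
                    * effects.get("n_clusters", 1.0)
                    * subj_mult
                )
                img_config = replace(
                    config.base,
                    n_clusters=int(rng.poisson(mean_clusters)),
                    cluster_sigma=config.base.cluster_sigma
                    * effects.get("cluster_sigma", 1.0),
                    locs_per_cluster=config.base.locs_per_cluster
                    * effects.get("locs_per_cluster", 1.0),
                    background_density=config.base.background_density
                    * effects.get("background_density", 1.0),
                )
                table, truth = simulate_image(img_config, seed=ss, image_id=image_id)
                tables[image_id] = table
                ground_truth[image_id] = truth
                manifest_rows.append(
                    {
                        "image_id": image_id,
                        "subject_id": subject_id,
                        "group": group,
                        "channel": config.base.channel,
                    }
                )
    manifest = CohortManifest(pd.DataFrame(manifest_rows))
    return CohortData(tables=tables, manifest=manifest, ground_truth=ground_truth)


def simulate_two_channel(
    config_A: SimulationConfig,
    config_B: SimulationConfig,
    overlap_fraction: float,
    seed: int,
    image_id: str = "sim-2ch",
) -> tuple[LocalizationTable, LocalizationTable, GroundTruth, GroundTruth]:
    """Simulate two registered channels of the same image.

    A fraction ``overlap_fraction`` of channel B's clusters is co-centred
    with channel A clusters; the remainder get fresh centres.  Both
    channels share the ROI (``config_A.roi_extent``).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if config_A.roi_extent != config_B.roi_extent:
        raise ValueError("both channels must share the same ROI extent")
    ss_a, ss_b = np.random.SeedSequence(seed).spawn(2)
    table_a, truth_a = simulate_image(config_A, seed=ss_a, image_id=image_id)

    n_shared = min(
        round(overlap_fraction * config_B.n_clusters), truth_a.n_clusters
    )
    preset = truth_a.centers[:n_shared] if n_shared else None
    table_b, truth_b = simulate_image(
        config_B, seed=ss_b, image_id=image_id, preset_centers=preset
    )
    return table_a, table_b, truth_a, truth_b
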