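"""Pre-clustering quality gates for localization tables.

Three gates are applied before any cluster detection, in this order:

1. photon-count threshold — keep localizations with PC >= ``min_photon_count``
   (default 1,000 photons; dim events localize poorly);
2. precision threshold — keep localizations with ``sigma_x`` <=
   ``max_sigma_x`` (default 100 nm);
3. PCA noise gate — a Mahalanobis-style outlier filter in the principal-axis
   frame of the 3D coordinate cloud: localizations farther than
   ``pca_sd_threshold`` standard deviations from the cloud centre (jointly,
   over all three principal axes) are discarded.

Both threshold gates use inclusive bounds.  The PCA gate at its default of
one standard deviation is strict — on an isotropic Gaussian cloud it retains
only P(chi2_3 <= 1) ~ 19.9% of points — which is why it is applied after the
quality thresholds and is switchable off.

The module also quantifies the precision–photon-count relationship
(:func:`precision_pc_correlation`): on well-behaved SMLM data the rank
correlation between PC and each precision axis is negative, since precision
improves roughly as 1/sqrt(PC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .loc_io import LocalizationTable

__all__ = [
    "FilterConfig",
    "FilterLog",
    "filter_by_photon_count",
    "filter_by_precision",
    "pca_noise_filter",
    "precision_pc_correlation",
    "apply_filters",
]


@dataclass(frozen=True)
class FilterConfig:
    """Configuration of the three quality gates.

    Attributes
    ----------
    min_photon_count:
        Minimum photon count, inclusive. Default 1,000 photons.
    max_sigma_x:
        Maximum x-axis localization precision, inclusive, nm. Default 100.
    pca_sd_threshold:
        Mahalanobis radius of the PCA gate, in standard deviations.
        Default 1.0.
    pca_enabled:
        Whether the PCA gate runs at all.
    """

    min_photon_count: float = 1000.0
    max_sigma_x: float = 100.0
    pca_sd_threshold: float = 1.0
    pca_enabled: bool = True

    def __post_init__(self) -> None:
        if self.min_photon_count < 0:
            raise ValueError("min_photon_count must be >= 0")
        if self.max_sigma_x <= 0:
            raise ValueError("max_sigma_x must be > 0")
        if self.pca_sd_threshold <= 0:
            raise ValueError("pca_sd_threshold must be > 0")


@dataclass
class FilterLog:
    """Per-stage localization counts, in application order."""

    stages: list[tuple[str, int, int]]  # (stage name, n before, n after)


def filter_by_photon_count(
    table: LocalizationTable, min_pc: float
) -> LocalizationTable:
    """Keep localizations with photon_count >= ``min_pc`` (inclusive)."""
    return table.select(table.photon_count >= min_pc)


def filter_by_precision(
    table: LocalizationTable, max_sigma_x: float
) -> LocalizationTable:
    """Keep localizations with sigma_x <= ``max_sigma_x`` (inclusive)."""
    return table.select(table.data["sigma_x"].to_numpy(dtype=float) <= max_sigma_x)


def pca_noise_filter(
    table: LocalizationTable, sd_threshold: float = 1.0
) -> LocalizationTable:
    """Mahalanobis outlier gate in the principal-axis frame of the cloud.

    Coordinates are centred, the covariance of (x, y, z) is
    eigendecomposed, and a localization is retained when its joint
    Mahalanobis distance satisfies ``d <= sd_threshold``.  On an isotropic
    Gaussian cloud the retained fraction equals the chi-square(3) CDF at
    ``sd_threshold**2``.

    Tables with fewer than 4 localizations, or with a degenerate
    (rank-deficient) coordinate covariance, are returned unchanged with a
    warning.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be > 0")
    n = len(table)
    if n < 4:
        warnings.warn(
            f"pca_noise_filter: only {n} localizations (< 4); returning input "
            "unchanged",
            stacklevel=2,
        )
        return table.with_data(table.data)
    coords = table.coords
    centred = coords - coords.mean(axis=0)
    cov = np.cov(centred, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[-1] <= 0 or eigvals[0] <= 1e-12 * eigvals[-1]:
        warnings.warn(
            "pca_noise_filter: degenerate coordinate covariance (collinear or "
            "coplanar cloud); returning input unchanged",
            stacklevel=2,
        )
        return table.with_data(table.data)
    scores = centred @ eigvecs / np.sqrt(eigvals)
    d2 = np.einsum("ij,ij->i", scores, scores)
    return table.select(d2 <= sd_threshold**2)


@dataclass
class CorrelationSummary:
    """Spearman correlation of photon count with each precision axis.

    ``defined`` is False when an axis is constant (rank correlation
    undefined), in which case ``rho`` is NaN — never silently zero.
    """

    rho: dict[str, float]
    p_value: dict[str, float]
    defined: dict[str, bool]
    n: int


def precision_pc_correlation(table: LocalizationTable) -> CorrelationSummary:
    """Spearman rank correlation between photon count and sigma_x/y/z."""
    n = len(table)
    if n < 3:
        raise ValueError("need at least 3 localizations for a rank correlation")
    pc = table.photon_count
    rho: dict[str, float] = {}
    pval: dict[str, float] = {}
    defined: dict[str, bool] = {}
    for axis in ("sigma_x", "sigma_y", "sigma_z"):
        s = table.data[axis].to_numpy(dtype=float)
        if np.ptp(s) == 0 or np.ptp(pc) == 0:
            rho[axis], pval[axis], defined[axis] = float("nan"), float("nan"), False
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.spearmanr(pc, s)
        rho[axis] = float(res.statistic)
        pval[axis] = float(res.pvalue)
        defined[axis] = bool(np.isfinite(res.statistic))
    return CorrelationSummary(rho=rho, p_value=pval, defined=defined, n=n)


def apply_filters(
    table: LocalizationTable, config: FilterConfig | None = None
) -> tuple[LocalizationTable, FilterLog]:
    """Apply the full gate sequence (PC -> precision -> PCA) and log counts."""
    config = config or FilterConfig()
    stages: list[tuple[str, int, int]] = []

    out = filter_by_photon_count(table, config.min_photon_count)
    stages.append(("photon_count", len(table), len(out)))

    before = len(out)
    out = filter_by_precision(out, config.max_sigma_x)
    stages.append(("precision", before, len(out)))

    if config.pca_enabled:
        before = len(out)
        out = pca_noise_filter(out, config.pca_sd_threshold)
        stages.append(("pca", before, len(out)))

    return out, FilterLog(stages=stages)
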