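"""Nonparametric two-group comparison of cohort metrics.

Design of the comparison mirrors a typical small dSTORM cohort (a handful
of subjects per group, ~10 images per subject): each subject is collapsed
to a vector of per-image metric values, and groups are compared with the
Mann–Whitney U test, which is exact at these sample sizes and makes no
distributional assumption.

Conventions, pinned because software disagrees on them:

* ``U_A = sum over pairs (a, b) of [a > b] + 1/2 [a == b]`` (midrank
  handling of ties); the *reported* ``U`` is ``min(U_A, U_B)``.
* Two-sided p-values. In ``exact`` mode the p-value is computed by full
  enumeration of all C(n_A+n_B, n_A) group assignments of the pooled
  sample (valid under ties), with the doubling rule
  ``p = min(1, 2*min(P(U_A <= u), P(U_A >= u)))``.  ``auto`` mode uses
  enumeration when ``n_A + n_B <= 16`` and otherwise the tie- and
  continuity-corrected normal approximation (delegated to
  ``scipy.stats.mannwhitneyu``).
* Comparison level: ``subject`` (default; one mean value per subject,
  matching the small-sample design) or ``image`` (one value per image).

No multiple-testing correction is applied to the headline p-values; the
multi-metric table adds a Benjamini–Hochberg column (``p_adj_bh``) purely
for transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .loc_io import CohortManifest

__all__ = [
    "SubjectVector",
    "GroupComparison",
    "mann_whitney_u",
    "build_subject_vectors",
    "subject_level_compare",
    "compare_metrics",
]

_EXACT_LIMIT = 16  # auto mode switches to the normal approximation above this
_ENUM_HARD_LIMIT = 26  # explicit exact mode refuses beyond this (C(26,13) ~ 10M)


@dataclass
class SubjectVector:
    """One subject's per-image metric values and their mean."""

    subject_id: str
    group: str
    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class GroupComparison:
    """Result of a two-group Mann–Whitney comparison."""

    metric: str
    level: str  # "image" or "subject"
    U: float  # min(U_A, U_B)
    u_A: float
    p_value: float
    method: str  # "exact" or "normal_approx"
    n_A: int
    n_B: int
    group_A: str
    group_B: str
    mean_A: float
    mean_B: float
    median_A: float
    median_B: float
    degenerate: bool = False


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U_A via midranks: R_A - n_A(n_A+1)/2."""
    n_a = len(a)
    ranks = stats.rankdata(np.concatenate([a, b]))
    return float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumeration of all group assignments."""
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    ranks = stats.rankdata(pooled)
    offset = n_a * (n_a + 1) / 2
    u_all = np.fromiter(
        (ranks[list(idx)].sum() - offset for idx in combinations(range(n), n_a)),
        dtype=float,
        count=math.comb(n, n_a),
    )
    eps = 1e-9
    p_le = np.mean(u_all <= u_obs + eps)
    p_ge = np.mean(u_all >= u_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def mann_whitney_u(
    sample_A,
    sample_B,
    mode: str = "auto",
    metric: str = "",
    level: str = "image",
    group_A: str = "A",
    group_B: str = "B",
) -> GroupComparison:
    """Two-sided Mann–Whitney U test between two independent samples."""
    a = np.asarray(sample_A, dtype=float)
    b = np.asarray(sample_B, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError("mode must be 'exact', 'normal_approx' or 'auto'")

    u_a = _u_statistic(a, b)
    u_b = a.size * b.size - u_a
    base = dict(
        metric=metric, level=level, U=min(u_a, u_b), u_A=u_a,
        n_A=int(a.size), n_B=int(b.size), group_A=group_A, group_B=group_B,
        mean_A=float(a.mean()), mean_B=float(b.mean()),
        median_A=float(np.median(a)), median_B=float(np.median(b)),
    )

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # all observations identical in both groups: no evidence either way
        return GroupComparison(p_value=1.0, method="degenerate", degenerate=True, **base)

    if mode == "auto":
        mode = "exact" if a.size + b.size <= _EXACT_LIMIT else "normal_approx"
    if mode == "exact":
        if a.size + b.size > _ENUM_HARD_LIMIT:
            raise ValueError(
                f"exact enumeration limited to n_A + n_B <= {_ENUM_HARD_LIMIT}"
            )
        p = _exact_p(a, b, u_a)
        return GroupComparison(p_value=p, method="exact", **base)

    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupComparison(p_value=float(res.pvalue), method="normal_approx", **base)


def build_subject_vectors(
    manifest: CohortManifest, summaries: pd.DataFrame, metric: str
) -> list[SubjectVector]:
    """Collapse per-image summaries into per-subject metric vectors.

    ``summaries`` must have an ``image_id`` column plus the metric column;
    every subject in the manifest must contribute at least one image.
    """
    if metric not in summaries.columns:
        raise ValueError(f"metric {metric!r} not in summaries columns")
    merged = summaries.merge(
        manifest.data[["image_id", "subject_id", "group"]].drop_duplicates("image_id"),
        on="image_id",
        how="left",
    )
    if merged["subject_id"].isna().any():
        missing = merged.loc[merged["subject_id"].isna(), "image_id"].tolist()
        raise ValueError(f"images not in manifest: {missing}")
    vectors = []
    for subject in manifest.subjects():
        vals = merged.loc[merged["subject_id"] == subject, metric].to_numpy(float)
        if vals.size == 0:
            raise ValueError(f"subject {subject!r} has no image summaries")
        vectors.append(
            SubjectVector(
                subject_id=subject,
                group=manifest.group_of_subject(subject),
                values=vals,
            )
        )
    return vectors


def subject_level_compare(
    manifest: CohortManifest,
    summaries: pd.DataFrame,
    metric: str,
    level: str = "subject",
    mode: str = "auto",
) -> GroupComparison:
    """Compare a metric between the manifest's two groups.

    ``level="subject"`` (default) tests one mean value per subject;
    ``level="image"`` tests per-image values directly.
    """
    if level not in ("subject", "image"):
        raise ValueError("level must be 'subject' or 'image'")
    groups = manifest.groups
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, manifest has {groups}")
    g_a, g_b = groups
    vectors = build_subject_vectors(manifest, summaries, metric)
    by_group: dict[str, list] = {g_a: [], g_b: []}
    for vec in vectors:
        if level == "subject":
            by_group[vec.group].append(vec.mean)
        else:
            by_group[vec.group].extend(vec.values.tolist())
    if not by_group[g_a] or not by_group[g_b]:
        raise ValueError("each group needs at least one subject with data")
    return mann_whitney_u(
        by_group[g_a], by_group[g_b], mode=mode,
        metric=metric, level=level, group_A=g_a, group_B=g_b,
    )


def compare_metrics(
    manifest: CohortManifest,
    summaries: pd.DataFrame,
    metrics: list[str],
    level: str = "subject",
    mode: str = "auto",
) -> pd.DataFrame:
    """One comparison row per metric, with a BH-adjusted p column added."""
    from statsmodels.stats.multitest import multipletests

    results = [
        subject_level_compare(manifest, summaries, m, level=level, mode=mode)
        for m in metrics
    ]
    df = pd.DataFrame(
        {
            "metric": [r.metric for r in results],
            "level": [r.level for r in results],
            "U": [r.U for r in results],
            "p_value": [r.p_value for r in results],
            "method": [r.method for r in results],
            "n_A": [r.n_A for r in results],
            "n_B": [r.n_B for r in results],
            "mean_A": [r.mean_A for r in results],
            "mean_B": [r.mean_B for r in results],
            "median_A": [r.median_A for r in results],
            "median_B": [r.median_B for r in results],
        }
    )
    # BH column is an addition for transparency; headline p-values are raw
    df["p_adj_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
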