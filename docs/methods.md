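# Methods

This note records the models, conventions and design choices behind
`stormclust`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the validation on synthetic data
does and does not establish.

## Data model and units

A localization is a fitted single-molecule position: coordinates
`(x, y, z)` in nm in an image-local frame, a photon count `PC > 0`, and
per-axis precisions `σ_x, σ_y, σ_z > 0` in nm. All I/O converts to nm at
ingestion (`Dialect.coordinate_unit`); no other module touches units.
Channels of one image are assumed registered by the microscope — no
registration is attempted. Missing `σ_y`/`σ_z` default to `σ_x` because
every quality gate acts on the x precision only; missing `channel`
defaults to `"default"`.

## Quality gates

Applied per image, in order:

1. **Photon count** — keep `PC ≥ min_photon_count` (default 1,000
   photons, inclusive). Dim blinks localize poorly; the precision–PC
   diagnostics (Spearman ρ between PC and each σ axis; negative on
   well-behaved data) make the rationale checkable per dataset.
2. **Precision** — keep `σ_x ≤ max_sigma_x` (default 100 nm, inclusive).
3. **PCA noise gate** (optional) — centre the coordinate cloud,
   eigendecompose its covariance, and keep points whose joint Mahalanobis
   distance in the principal-axis frame is ≤ `pca_sd_threshold` (default
   1.0 SD). On an isotropic Gaussian cloud the retained fraction equals
   the χ²₃ CDF at the squared threshold — **≈ 19.9 % at 1 SD**. This gate
   is deliberately aggressive and models a *single compact structure per
   image*; on multi-structure images it trims everything outside the
   central ellipsoid, so it is a config switch (`pca_enabled`) and the
   cohort pipeline defaults used in the acceptance script leave it off
   for cluster detection while calibrating it separately. The gate is
   joint over the three principal axes (not per-axis) and uses
   coordinates only, not PC. Inputs with < 4 points or a rank-deficient
   covariance are returned unchanged with a warning.

Both threshold gates use inclusive bounds, are idempotent, commute, and
only ever remove rows (order preserved) — tested as algebraic properties.

## DBSCAN

Standard density-based clustering on the 3D Euclidean metric. Pinned
conventions: `min_pts` counts the point itself; the `eps` bound is
inclusive; border points join the cluster of the first core point (input
order) that reaches them; noise is `-1`. The production path wraps
`sklearn.cluster.DBSCAN`, which implements exactly these semantics; an
independent O(n²) brute-force implementation (full distance matrix, core
set, connected components of the core graph) serves as a verification
oracle. Equivalence is tested on random blob+background instances: core
sets must match exactly, partitions up to relabeling, with ambiguous
border points (reachable from cores of two clusters) excluded from the
comparison since their assignment is legitimately order-dependent.
Defaults `eps = 75 nm`, `min_pts = 10` target the tens-to-hundreds-of-nm
aggregate regime; an optional `z_scale` compensates anisotropic axial
precision (default 1.0).

## FOCAL and the photon-count gate

Plain FOCAL: voxelize at `voxel_size` (origin at the per-axis minimum
coordinate, `floor((coord − origin)/voxel_size)`); score each occupied
voxel with the summed localization count of itself plus its 26
neighbours; core voxels have score ≥ `minL`; candidate clusters are
26-connected components of core voxels; components with ≥ `minC` voxels
are clusters; member localizations inherit the component id.

`FOCAL^PC` gates on voxel-mean photon count: voxels with mean PC
strictly above `maPC` survive; within each candidate the surviving
voxels are re-grouped by connectivity, and a surviving sub-group is kept
when it has ≥ `minC` voxels and contains a voxel whose score, recomputed
over the *surviving voxel set*, is ≥ `minL`. Two consequences, both
enforced by tests:

* with `maPC = 0` every occupied voxel survives (PC > 0), so the output
  is bit-identical to plain FOCAL;
* raising `maPC` only removes voxels and only lowers re-scored
  occupancies, so the clustered-localization set is nested
  (monotonically shrinking) in `maPC`.

Re-scoring over the full surviving set, rather than over each sub-group
in isolation, is the choice that makes both properties exact; scoring
within a sub-group alone can demote a core voxel merely because its
neighbours were non-core, breaking the `maPC = 0` identity.

Choices that the original grid-clustering idea leaves open, and what this
implementation pins:

* **Voxel size** — default 50 nm, ≈ 2–3× a typical 10–20 nm lateral
  precision: coarse enough that a voxel's occupancy is statistically
  meaningful, fine enough to resolve ~100 nm aggregates. Fully exposed;
  all structural guarantees hold for any value.
* **Scoring kernel** — neighbourhood sum (self + 26) by default, with a
  `kernel="self"` switch.
* **Connectivity** — 26 (face+edge+corner) by default; 6 available. The
  same connectivity is used for scoring and for components.
* **Grid origin** — deterministic per-image minimum; no multi-offset
  grid averaging. Shifting all coordinates by any multiple of
  `voxel_size` reproduces the partition exactly (tested).
* **Determinism** — components are enumerated from their
  lexicographically smallest voxel, so labels never depend on hash
  order; identical input + parameters give identical output.
* Defaults `minL = 10`, `minC = 3` recover simulated aggregates of
  ~200 localizations over sparse background; like all FOCAL parameters
  they are dataset-dependent and exposed everywhere.

An independently coded, deliberately literal transcription of the six
steps lives in the test suite and must agree with the implementation on
random instances, gated and ungated.

## Cluster morphometrics

* **Radius** — 3D radius of gyration (RMS distance to the centroid);
  singletons have radius 0. Reference values used in tests: two points
  `d` apart → `d/2`; uniform ball of radius `R` → `R√(3/5)`; isotropic
  Gaussian with per-axis σ → `σ√3`. A max-distance-to-centroid
  alternative (`definition="max"`) probes sensitivity.
* **Density** — `n / ((4/3)π r³)` with the gyration radius
  (`density_raw`, nm⁻³), its ×1,000 "platform" rescaling
  (`density_platform`, exact by construction), and a 2D projected
  variant `n / (π r²)` (nm⁻²). Both 3D and 2D forms are emitted because
  aggregate densities are reported in either unit in the literature.
  Coincident-point clusters (r = 0, n ≥ 2) get infinite density, are
  flagged, and are excluded from image means with a warning. Note that
  1/r³ makes per-cluster density heavy-tailed when strict gating leaves
  few-localization cores; image means of density should be read with
  that in mind.
* **ROI volume** — convex hull by default (tightest deterministic proxy
  of the imaged region), falling back to the bounding box with a warning
  on degenerate geometry; user-supplied box bounds also supported.
  Localization counts are normalized per ROI volume to compare images
  with different fields.

Per-image summaries conserve counts (Σ cluster sizes + noise = total)
and report the percentage of localizations assigned to clusters.

## Two-channel ratios

Per image, the marker (e.g. PGP9.5) channel's occupied volume and
localization count are divided by the aSyn channel's (marker in the
numerator). "Occupied volume" is the channel's convex-hull volume by
default; a voxel-occupancy variant (occupied voxels × voxel volume,
voxel size shared with FOCAL) is provided because hulls overestimate
sparse branched structures such as nerve fibres. A volume *difference*
is emitted alongside the ratio so either reading of a volume comparison
is available. Undefined ratios (empty denominator) are flagged NaN,
never dropped; cohort tables exclude images missing a channel with a
logged warning and refuse to proceed if no complete pair exists.

## Group comparison

Subjects are collapsed to vectors of per-image metric values; the
default comparison level is one mean per subject (appropriate for
small cohorts and avoiding pseudo-replication of images within
subjects), with an image-level option recorded in every result. The test
is the two-sided Mann–Whitney U: `U_A = Σ [a > b] + ½[a = b]`; reported
`U = min(U_A, U_B)`. Exact p-values are computed by full enumeration of
all `C(n_A+n_B, n_A)` group assignments of the pooled sample (valid
under ties) with the doubling rule `p = min(1, 2·min(P(U ≤ u),
P(U ≥ u)))`; `auto` mode enumerates up to `n_A + n_B = 16` and otherwise
uses the tie- and continuity-corrected normal approximation
(scipy). Degenerate input (all values identical) returns p = 1 with a
flag. Exchangeability (swapping groups maps `U_A → n_A n_B − U_A`,
p unchanged) and invariance under monotone transforms are tested
properties; the exact mode is cross-checked against scipy's exact method
(tie-free data) and an independent pair-counting enumeration. No
multiple-testing correction is applied to headline p-values; the
multi-metric table adds a Benjamini–Hochberg column purely for
transparency.

Type-I calibration: on simulated null cohorts (6 vs 6 subjects × 10
images, subject-level heterogeneity but no group effect) the
subject-level rejection rate at α = 0.05 sits within binomial error of
the nominal level over 200 replicates (tested). Slight conservatism is
expected from the discreteness of the exact test at n = 6 + 6.

## The simulator: what it emulates, and what it does not

`simulate_image` plants isotropic Gaussian nano-clusters (default
per-axis σ = 40 nm → gyration radius ≈ 69 nm, inside the 40–200 nm
radius range typical of reported aggregates) at uniform centres with a
rejection-enforced minimum separation (4σ), Poisson member counts
(default mean 200), and uniform Poisson background (default
5×10⁻⁷ nm⁻³ over a 10 × 10 µm × 600 nm ROI). Photon counts are
lognormal (median 1,500 photons, log-sd 0.5); inside clusters they are
multiplied by `cluster_pc_multiplier` (default 6) attenuated radially as
`multiplier^exp(−r²/2σ²)` — bright aggregate cores, dimming toward the
periphery — which is the structure a voxel-mean photon-count gate
exploits and the reason raising `maPC` peels aggregates from the outside
in. A `"flat"` profile is available. Precision follows the photon-limited
scaling `σ_x = σ_y = s₀/√PC` (s₀ = 700 nm·√photons, giving 10–20 nm at
typical counts) with `σ_z = 2σ_x` (biplane-like axial penalty).
`simulate_cohort` adds subject-level lognormal heterogeneity (sd 0.15 on
the log cluster count) and per-group effect multipliers;
`simulate_two_channel` co-centres a chosen fraction of channel B's
clusters on channel A's. Everything is deterministic given a seed.

Not emulated: blinking/re-blinking kinetics (so localization counts are
not molecule counts), drift, anisotropic or fibril-shaped aggregates,
detector noise, and spatially varying background. Consequently, passing
tests establish the *algorithmic* correctness and the stated statistical
calibrations of the pipeline — they do not certify biological effect
sizes, and analyses of real biopsy data still require dataset-specific
parameter tuning (voxel size, minL/minC, eps/min_pts are not printed
constants of nature).

## Problem sizes and numerics

Validation runs use desk-scale problems chosen to make the statistics
decisive: oracle equivalence on 50–100 random instances of ≤ ~200–500
points; planted-cluster recovery with 20 clusters × 200 localizations
over 10 % background; χ² calibration at n = 10⁴; type-I calibration
over 200 replicate cohorts of 120 small images; the acceptance script
simulates a 6 + 6 × 10-image cohort of 30-cluster images. Floating-point
ties at voxel boundaries resolve by `floor`; exact-enumeration p-values
compare with a 10⁻⁹ tolerance on U; convex hulls use Qhull via scipy
with explicit degenerate-geometry fallbacks.
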