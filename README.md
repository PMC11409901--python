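# stormclust

Cluster analysis of 3D dSTORM (direct stochastic optical reconstruction
microscopy) localization data, built for quantifying nanoscale protein
aggregates — e.g. alpha-synuclein deposits in skin-biopsy nerve fibres —
and comparing them between subject groups.

A dSTORM experiment yields, per image, a table of *localizations*: fitted
single-molecule positions `(x, y, z)` in nm, each with a photon count
(PC, the detected brightness of the blink) and a per-axis localization
precision `σ_x, σ_y, σ_z`. `stormclust` takes such tables through quality
filtering, cluster detection, aggregate morphometry, two-channel ratio
analysis, and nonparametric group statistics, and ships a ground-truth
simulator so that every stage is verifiable without microscope data.

## The core algorithm: FOCAL with a photon-count gate

FOCAL (fast optimized cluster algorithm for localizations) bins
localizations into a cubic voxel grid (edge `voxel_size`, default 50 nm)
and scores each occupied voxel with the localization count of the voxel
plus its 26 neighbours. Voxels with score ≥ `minL` are *core*;
26-connected components of core voxels with ≥ `minC` voxels are clusters.

The photon-count extension `FOCAL^PC` adds a gate: only voxels whose
*mean* photon count exceeds `maPC` (strictly) survive; within each
candidate cluster the survivors are re-grouped by connectivity and each
surviving sub-group must again satisfy `minC` and contain a core voxel
under scores recomputed on the surviving voxel set. Because precision
improves with photon count (σ ∝ 1/√PC), the gate preferentially keeps the
well-localized interior of an aggregate: raising `maPC` peels off dim,
spatially loose periphery, so detected aggregates get smaller and denser,
and the set of clustered localizations is provably nested in `maPC`.
`maPC = 0` disables the gate exactly.

Also included:

* quality gates: PC ≥ 1,000 photons, `σ_x` ≤ 100 nm, and an optional
  1-SD Mahalanobis (PCA) outlier gate, with Spearman diagnostics of the
  precision–PC relation;
* DBSCAN (via scikit-learn) with a hand-written O(n²)
  density-reachability oracle for verification;
* per-cluster metrics: gyration radius, localizations per cluster, 3D
  density `n / ((4/3)πr³)` (also ×1,000 "platform" scale and a 2D
  projected variant), convex-hull ROI volumes;
* two-channel marker/aSyn volume and count ratios;
* exact (full-enumeration) Mann–Whitney U comparison of per-subject or
  per-image metrics;
* a seeded simulator of clustered + background localizations with
  PC–precision coupling, two channels, and hierarchical two-group
  cohorts.

## Worked example

Simulate one image of 20 aggregates (Gaussian spread 40 nm → gyration
radius ≈ 69 nm, ~200 localizations each) over a uniform background,
filter it, and sweep the photon-count gate:

```python
from stormclust import (SimulationConfig, simulate_image, FocalParams,
                        FilterConfig, apply_filters, sweep_maPC)

config = SimulationConfig(
    roi_extent=(5000.0, 5000.0, 600.0),
    n_clusters=20,
    locs_per_cluster=200,
    cluster_sigma=40.0,
    background_density=3e-7,
)
table, truth = simulate_image(config, seed=1, image_id="demo")
print(f"{len(table)} localizations, {truth.n_clusters} planted clusters")

filtered, log = apply_filters(table, FilterConfig(pca_enabled=False))
for stage, before, after in log.stages:
    print(f"  {stage}: {before} -> {after}")

sweep = sweep_maPC(filtered, FocalParams(voxel_size=50, minL=10, minC=3),
                   [0, 2500, 5000])
print(sweep.round(2).to_string(index=False))
```

prints

```
8334 localizations, 20 planted clusters
  photon_count: 8334 -> 7163
  precision: 7163 -> 7163
  maPC  n_clusters  mean_radius_nm  mean_density_platform  mean_locs_per_cluster  pct_locs_clustered
   0.0          20           67.43                   0.15                 186.05               51.95
2500.0          20           57.15                   0.17                 134.55               37.57
5000.0          17           37.20                   0.21                  43.76               10.39
```

The PC filter removes the dim quarter of the localizations (the
simulated PC distribution straddles the 1,000-photon cutoff); the
precision filter is already implied by it here, since σ = 700/√PC ≤ 100 nm
whenever PC ≥ 49. All 20 planted aggregates are found at `maPC = 0` with
mean gyration radius ≈ 67 nm (truth: 69 nm). Raising `maPC` to 2,500 and
then 5,000 photons trims each aggregate to its bright core: mean radius
falls (67 → 57 → 37 nm), mean density rises (0.15 → 0.17 → 0.21 on the
×1,000 platform scale), and fewer localizations stay clustered.

There is also a CLI mirroring the pipeline stages
(`stormclust simulate | filter | cluster | metrics | ratios | compare |
run`); `stormclust run --config pipeline.yaml` executes
filter → cluster → metrics → group comparison for a whole cohort and
writes per-image tables plus a provenance record.

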