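# attiscan

Surface-attitude statistics from spherical LiDAR scans.

`attiscan` is a tested, reusable pipeline that

1. **simulates** eye-height (1.65 m) spherical range scans of parametric
   scenes — indoor rooms, outdoor built, outdoor natural — including
   back-to-back scan pairs with injected moving objects,
2. **cleans** scan pairs: azimuthal alignment by circular range
   cross-correlation, mover removal via bimodal range-contrast
   thresholding inside bounding boxes, and a low-intensity return filter,
3. **estimates** per-point surface normals by PCA plane fitting with
   iterative 3-sigma outlier rejection and *minimum-reliable-scale*
   neighbourhood selection (k = 7..300, planarity thresholds calibrated
   on scans of known planes),
4. **aggregates** egocentric slant/tilt probability densities on an
   area-preserving hemisphere map, conditioned on scene category and view
   elevation band, and compares them against the closed-form
   maximum-entropy (random-world) attitude model, and
5. **co-registers** two sensor frames from three target correspondences
   (closed-form Wahba initialization + joint nonlinear refinement).

## Conventions

* Sensor at the origin, +Z is world up (the scanner self-levels);
  azimuth counter-clockwise from +X; elevation measured from nadir
  (0° straight down, 90° horizon, 180° zenith). Default scans cover
  elevations 45°–180° (the tripod occludes lower elevations).
* Slant φ ∈ [0°, 90°]: angle between the viewer-facing normal and the
  anti-view direction. Tilt θ ∈ [0°, 360°): clockwise angle of the
  normal's image-plane projection from the egocentric upward axis —
  floor 0°, left/right walls 90°/270°, ceiling 180°.
* World slant ∈ [0°, 180°]: angle of the normal from world up.
* The equal-area map uses φ′ = √(2(1 − cos φ)), θ′ = θ; under the
  foreshortened random-world model the slant marginal is sin 2φ (peak at
  45°) and the fixed-tilt conditional is cos φ.
* Degrees at API boundaries, radians internally.

## CLI

```sh
attiscan simulate  --category indoor --seed 1 --out scene        # scan pair
attiscan clean     --scan1 scene_scan1.npz --scan2 scene_scan2.npz \
                   --out cleaned.npz --pcd cleaned.pcd
attiscan normals   --scan cleaned.npz --out normals.npz
attiscan stats     --category indoor --seed 1 --out run/
attiscan maxent    --out maxent.txt                              # analytic curves
attiscan coregister --targets targets.txt --out transform.txt
attiscan full-run  --config config.yaml --out run/               # whole pipeline
```

All stages are deterministic given the config and seeds; `full-run`
writes per-category density files (JSON with binning metadata), a
calibration table, and a `summary.json` with per-stage point-conservation
counts.

Config is a YAML file mirroring `attiscan.config.PipelineConfig`; e.g.

```yaml
scan: {step_arcmin: 30.0, range_noise_m: 0.001}
categories: [indoor, outdoor-built, outdoor-natural]
scenes_per_category: 2
max_query_points: 20000
seed: 0
```

Point clouds are read/written as PCD (x, y, z, intensity); returns
deleted by cleaning are written as all-zero `[0, 0, 0, 0]` records.

## Layout

| module | role |
| --- | --- |
| `attiscan.geometry` | egocentric frames, slant/tilt, equal-area map, maxent model |
| `attiscan.scenes` | parametric scenes and spherical ray casting |
| `attiscan.artefacts` | scan-pair alignment, mover removal, intensity filter |
| `attiscan.normals` | plane fits, noise calibration, adaptive scale selection |
| `attiscan.stats` | attitude densities, marginals, maxent comparison |
| `attiscan.coregister` | rigid transform from three target correspondences |
| `attiscan.io` / `attiscan.cli` / `attiscan.config` / `attiscan.pipeline` | I/O, CLI, configuration, orchestration |
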