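# cortmap

Cortical bone thickness (CBT) mapping and tibial morphometry from CT, with a
synthetic phantom and cohort generator that supplies ground truth for every
stage — so the whole pipeline is testable without any patient data.

## What it does

In varus knee osteoarthritis the load concentrates on the medial compartment,
and the cortical shell of the tibial shaft remodels in response. Quantifying
that remodelling needs three measurements per subject, all implemented here:

1. **Sub-voxel cortical thickness.** Along each surface normal the CT
   intensity is modelled as two Gaussian-blurred steps between three density
   levels (soft tissue `y0`, cortex `y1`, trabecular bone `y2`):

   `y(x) = y0 + (y1−y0)·Φ((x−x0)/σ) + (y2−y1)·Φ((x−x1)/σ)`

   with thickness `t = x1 − x0` and scanner blur `σ`. Because a thin cortex
   never reaches its true peak density, a free fit of `y1` is biased; the
   estimator therefore runs two passes — free-`y1` fits, a robust global
   cortical-density estimate pooled from the thick cortices (`t ≥ 3σ`), and a
   fixed-`y1` refit — which recovers thickness well below the voxel size.
2. **Anatomical frame and 24-region aggregation.** A tibial coordinate system
   is built from least-squares circle centres in two diaphyseal sections plus
   the PCL-attachment → tibial-tuberosity line; the 30–70% band of tibial
   length is split into 6 height bands × 4 axial sectors and the per-region
   mean thickness is standardized by tibial length (×10⁻³).
3. **Alignment morphometry.** The femorotibial angle (FTA, >180° = varus) from
   total-least-squares anatomical axes through cross-section centroids, and
   the coronal inclination of the medial tibial plateau (MCT) from the
   least-squares plane through eight digitized plateau points.

A statistics layer reproduces the study design: Shapiro–Wilk-gated test
selection (RM-ANOVA/Friedman within groups, ANOVA/Kruskal–Wallis between
groups, Pearson/Spearman correlations), variance-components ICC reliability,
and an exact-power sample-size calculation for correlation outcomes.

## Worked example

```bash
python analysis/01_build_phantom.py
python analysis/02_map_thickness.py
```

prints, for the default phantom (330 mm tibia, uniform 5 mm cortex,
densities 0/1200/300 HU, σ = 0.9 mm, 0.7×0.7×1.0 mm voxels, 15 HU noise):

```
vertices fitted: 1920  converged: 1920
global cortical density: 1201 HU (truth 1200)
mean thickness: 5.028 mm (truth 5.000)
```

i.e. the pooled density estimate lands within 0.1% of truth and the mapped
thickness within 0.03 mm at this noise level. Continuing,

```bash
python analysis/04_alignment_morphometry.py
python analysis/06_power_analysis.py
```

```
FTA: 187.00 deg (constructed varus -> truth 187.0)
MCT coronal angle: 12.199 deg (truth 12.2)
OA male: rho=0.594  minimal n (exact) = 19 (power 0.804); Fisher-z cross-check = 20
OA female: rho=0.554  minimal n (exact) = 23 (power 0.815); Fisher-z cross-check = 24
```

The 7° constructed varus phantom returns an FTA of exactly 187°, the plateau
plane recovers its 12.2° coronal tilt, and the exact-power calculation gives
the minimal cohort sizes (19 and 23 tibias) for the two correlation outcomes.
`analysis/03_regional_cbt.py` writes the 24-region table and the M/L–A/P
ratio table; `analysis/05_cohort_statistics.py` generates the four-group
cohort and runs the gated statistics on it. The same stages are available as
a CLI (`cortmap all --outdir results/run --seed 1`).

## Layout

- `src/cortmap/` — library: `phantom` (synthetic volumes/profiles/cohorts),
  `cbt` (surface extraction + thickness estimation), `anatomy` (tibial frame),
  `regions` (24-region aggregation), `morphometry` (FTA/MCT), `stats`
  (gated tests, ICC, exact power), `pipeline`/`cli` (orchestration),
  `benchmark` (the 500-profile accuracy benchmark).
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `tests/` — unit, property and acceptance suites with brute-force oracles.
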