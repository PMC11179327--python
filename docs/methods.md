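# Methods

## Profile model and thickness estimation

The intensity along a line crossing the cortex perpendicular to the surface
is modelled as a three-level density profile blurred by the scanner PSF,

y(x) = y0 + (y1 − y0)·Φ((x − x0)/σ) + (y2 − y1)·Φ((x − x1)/σ),

where x (mm) runs along the inward normal (x = 0 at the nominal surface
crossing, negative outside the bone), y0/y1/y2 are the soft-tissue, cortical
and trabecular densities (HU), x0/x1 the outer and inner cortical edges,
t = x1 − x0 the thickness and σ the Gaussian blur width. Φ is the standard
normal CDF.

Fitting is bounded nonlinear least squares (trust-region reflective). Edges
are initialized at the extreme-gradient positions of the profile smoothed by
one sample; σ starts at 1 mm. Default bounds: t ∈ [0.3, 15] mm,
σ ∈ [0.2, 3] mm; a fit is flagged non-converged when the optimizer fails or
the solution sits on the t or σ bounds.

**Why two passes.** When t ≲ 2σ the blurred peak never reaches y1, so y1 and
t are jointly unidentifiable and a free fit trades one for the other. Pass 1
fits every profile with y1 free; the global cortical density is the median y1
over converged fits with t ≥ 3σ (where the peak saturates and y1 is readable);
pass 2 refits every profile with y1 fixed at that value. This constant-density
assumption is what buys sub-voxel accuracy: on the standard benchmark (500
profiles, t ~ U(1,8) mm, σ ~ U(0.6,1.3) mm, 0.7 mm spacing, 20 HU noise) the
two-pass estimator reaches a mean absolute error of ≈ 0.05 mm, versus
≈ 0.23 mm for the free fits, with |bias| < 0.02 mm for t ≥ 2 mm.

Profile geometry defaults: half-length 9 mm either side of the vertex,
0.3 mm sample spacing (the benchmark uses a 12 mm half-length so the widest
cortex plus 3σ of trailing edge stays inside the line). Profiles leaving the
volume are trimmed and flagged; vertices whose line cannot be sampled are
recorded as non-converged rather than aborting the map.

## Surface extraction

The outer surface is extracted as per-slice sub-pixel iso-contours (linear
interpolation at the threshold), with the largest closed contour per slice
resampled to a fixed number of points by azimuth about its centroid and
consecutive rings triangulated. The default threshold is the midpoint of the
low (1st percentile) and high (99.5th percentile) intensity estimates — for a
blurred step this places the iso-surface at the true edge position. Normals
are recomputed from the mesh and oriented outward against the per-ring
centroid. The azimuthal resampling assumes near-convex sections, which holds
for the tubular phantom this package ships; a general marching-cubes
extractor meeting the same sub-voxel vertex-error contract would be a drop-in
replacement.

Note on discretization: trilinear interpolation of a σ = 0.9 mm blurred
1200 HU edge sampled at 0.7 mm voxels carries ≈ 20 HU RMS of structured error
(h²/8·max|y″|). This is a property of the sampling scale, not of the fit; it
perturbs recovered thickness by only a few hundredths of a millimetre because
the error is smooth and largely symmetric about the edges.

## Anatomical tibial frame

Temporal z-axis: the line joining least-squares (Kasa) circle centres fitted
to the cortex cross-sections in two transverse planes, by default at 30% and
70% of tibial length (the diaphysis limits; the source description does not
fix the planes). Section points are mesh vertices within a ±2.5 mm slab of
the plane, which makes the construction exactly equivariant under rigid
motion of the inputs. y-axis: PCL attachment → medial tuberosity edge,
projected orthogonal to the temporal z and normalized (positive anterior).
The published axis chain (x from "temporal z × y", z from "y × x") yields a
negated x when z is superior and y anterior; the canonical right-handed
resolution used here is x = y × z_temporal (positive right) and
z = x × y (= temporal z exactly, since y was orthogonalized first). Anyone
comparing frames with the original navigation software should check the sign
of x. The origin is the most distal intersection of the true z-axis with the
distal articular surface patch (Möller–Trumbore over the patch triangles).
Left tibiae keep the same frame (x positive right in patient space); side
handling happens at sector assignment, not in the frame.

## Regions and standardization

Tibial length L is the distance from the midpoint of the tibial eminence
points to the midpoint of the medial/lateral talar-dome points. Height
fraction is measured along the frame z-axis from the projected talar-dome
midpoint. Bands: most distal 30–37%, distal 37–43%, central distal 43–50%,
central proximal 50–57%, proximal 57–63%, most proximal 63–70%; half-open
[lo, hi) with the top band closed at 70% (so 0.50 falls in central proximal).
Sectors are 90° wedges about the medial (x_eff = −x right side / +x left),
anterior (+y), lateral and posterior directions, half-open counterclockwise
(an exact 45° boundary point is anterior). Ties affect < 0.2% of phantom
vertices; the convention is fixed so runs are reproducible. Regional values
are arithmetic means of converged vertices only, with counts reported;
regions under 20 points are flagged low-count but still reported.
Standardized thickness is mean/L × 10³; M/L and A/P ratios are ratios of
sector means per band and over the whole diaphysis.

## Alignment morphometry

Anatomical axes: area centroids (shapely, on the section polygon) of
cross-sections at planes dividing the 30–70% diaphysis band into 11 (femur)
or 13 (tibia) equal sections — 10 and 12 interior planes respectively — then
a total-least-squares 3D line (first principal direction). FTA: both
directions projected onto the femoral coronal (xz) plane, femoral direction
oriented distally, tibial distally; FTA = 180° + the signed deviation of the
tibial direction from the prolonged femoral axis, positive toward the midline
(varus). The 180° anchor and sign follow the published magnitudes (healthy
≈ 175–179°, OA ≈ 187–189°) and the stated "larger angle = more varus". The
femoral frame is an input contract (the phantom supplies it).

MCT: orthogonal least-squares plane (smallest principal component) through
the digitized plateau points; the coronal inclination is the acute angle
between the tibial x-axis and the intersection line of that plane with the
tibial xz-plane — for z = c + b·x this is arctan|b| exactly, and any sagittal
tilt cancels. The source text also contains a sentence reading "smaller
angles indicate greater inclination", which contradicts the geometric
definition and the published group means; the implementation follows the
geometry (larger coronal angle = steeper medial slope).

## Statistics

Every test is gated by Shapiro–Wilk at α = 0.05 (per margin, per group, or on
the within-subject residuals; the gate level is a package choice and is
recorded in every report). Within-group area comparison: two-way
within-subject ANOVA (closed-form sums of squares; cross-checked against
pingouin) with paired-t/Holm post hoc, or Friedman with Wilcoxon/Holm.
Between groups: one-way ANOVA with Tukey HSD, or Kruskal–Wallis with
Dunn/Holm. Correlation: Pearson when both margins pass, else Spearman.
ICC: two-way mixed consistency single measures (ICC3,1) for intra-rater
repeats, two-way random absolute agreement single measures (ICC2,1) across
raters, via variance components (pingouin).

Sample size for a correlation: the exact density of the sample correlation
under bivariate normality (Gaussian-hypergeometric form, log-stabilized) is
integrated over the two-sided rejection region |r| > r_crit(n, α) of the
t-test of zero correlation; the minimal n ≥ 4 reaching the target power is
returned. A closed-form evaluator makes Monte-Carlo replication unnecessary;
the Fisher-z approximation is provided as an independent cross-check and
agrees within one subject over ρ ∈ [0.3, 0.7]. At α = 0.05 and power 0.80
the exact evaluator returns n = 19 at ρ = 0.594 and n = 23 at ρ = 0.554.

## Synthetic phantom and cohort

The phantom is a tapered cortical tube along z: outer radius
13 + 3·(2h−1)² mm over height fraction h (mild flare at both ends), default
uniform 5 mm cortex, densities (0, 1200, 300) HU — representative of soft
tissue, cortical and trabecular attenuation on the scanners of interest —
σ = 0.9 mm PSF, 0.7×0.7×1.0 mm voxels, 15 HU noise, 330 mm length (an adult
tibia). The three-level labelled volume is blurred by an isotropic Gaussian
and noise is added with a seeded generator; identical specs are bit-identical.
Landmarks (eminence, talar dome, PCL attachment, tuberosity edge, distal
articular patch) are placed symmetrically so the ground-truth frame is the
identity. Alignment meshes realize a chosen varus angle by hinging a straight
femur at the knee. Plateau points are scattered over a 5–35 mm (ML) ×
±20 mm (AP) medial footprint on the plane z = c + b·x + a·y, with
digitization noise in z.

What the phantom does *not* emulate: trabecular texture, marrow
heterogeneity, cortical porosity, beam hardening, metal artifacts, non-tubular
metaphyseal geometry, or osteophytes. Passing tests therefore demonstrate the
correctness of the estimators under the stated imaging model, not their
robustness to every pathology of clinical CT.

The cohort generator draws per-group demographics, FTA, MCT and 24 regional
standardized-CBT values from normal marginals truncated to physical ranges
(bounds several SD from every mean, so sample moments still converge to the
spec values). The MCT angle and the most proximal-medial thickness are drawn
jointly Gaussian with the group correlation ρ (defaults 0.594 / 0.554 for the
OA groups, −0.211 / 0.164 for the healthy groups, from the published
correlation table); other regions are independent given the group — the
published tables give only marginal moments and this one correlation, so no
further dependence structure is imposed. Regional SDs are back-computed from
printed 95% CIs as √n·halfwidth/1.96.

## Problem sizes and numerical choices

The default pipeline maps ~1,900 diaphyseal vertices (40 per ring, 3 mm ring
spacing, band 28–72% of length) out of a ~4,400-vertex full-bone mesh,
matching the scale of the published per-subject point counts; vertex density
is configurable. Map estimation is restricted to the diaphysis band because
the regional analysis uses only 30–70%. Surface smoothing
(`filter_thickness_map`) uses Gaussian weights over a Euclidean
neighbourhood ball, a faithful stand-in for the geodesic ball at radii far
below the tube diameter; it is off by default (radius 0) since regional
averaging already pools tens of vertices. Degenerate inputs (collinear
circle/plane points, coincident centroids, constant stats margins, zero
variance) raise errors naming the cause rather than returning silent NaNs.
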