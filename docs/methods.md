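# Methods

`mitoscreen` re-implements a screenable fibroblast assay for
mitochondrial morphology and membrane potential as a tested pipeline.
One observation unit is a 3-channel 2D fluorescence tile: Hoechst
(nuclei), TMRM (mitochondria; fluorescence tracks membrane potential
Ψm in subquenching mode), and CellMask deep red (plasma membrane).
Per-mitochondrion morphometrics are aggregated to cells and subjects,
compared between a case group (idiopathic Parkinson's disease
fibroblasts in the motivating assay) and controls with a
distribution-adaptive testing scheme, and fed to an SVM classifier
with leave-one-subject-out cross-validation.

## Segmentation

* **Nuclei** — Hoechst is low-pass filtered with a truncated 10×10
  Gaussian kernel of σ = 2 px (kernel normalized to unit sum; the even
  kernel size shifts the response half a pixel, which is irrelevant for
  counting and labelling), thresholded strictly at >100 intensity
  units, 8-connected labelled, and components with *fewer than* 500 px
  removed. All size filters in the package are strict in this sense: a
  component of exactly the cutoff size survives.
* **Cell area** — difference of Gaussians (DoG, σ = 4/40 px) on the
  CellMask channel, threshold 60, minimum size 200 px. The DoG sigmas
  and threshold are not dictated by the assay description; the defaults
  were fixed once against the built-in simulator and are exposed in
  `PipelineConfig`.
* **Mitochondria (MitoMask)** — DoG (σ = 1/4 px) on the TMRM channel,
  minimum size 6 px. The threshold may be a fixed intensity (plate-wide
  convention) or `"auto"` (default): half of the 99.5th percentile of
  the DoG response, floored at six robust sigmas (MAD). The per-tile
  option exists because TMRM dims globally under FCCP; a single fixed
  cut cannot serve both conditions.
* **Cell splitting** — connected components of the cell-area mask are
  checked by nucleus counting. Components with two or more nuclei are
  split by grey-tone erosion of the (σ = 2 smoothed) CellMask intensity
  with a disk of radius 12 px, iterated up to `max_iterations` (20);
  after each pass the eroded image is re-thresholded (escalating
  schedule: base threshold × {1, 1.25, 1.5, 1.75, 2}, because a neck
  shadowed by a brighter neighbour only separates at a higher cut) and
  the parts' nucleus counts are evaluated. When every nucleus falls in
  its own part, the parts seed a geodesic nearest-seed re-attachment of
  all original component pixels, so foreground area is conserved
  exactly. Non-converged components are flagged in the QC table, never
  silently kept as successes; zero-nucleus components are discarded;
  border-touching cells are flagged. Pre-smoothing is required because
  a min filter otherwise tracks shot-noise minima.
* Mitochondria are assigned to the cell holding the plurality of their
  pixels; mitochondria mostly outside all cells are dropped and logged.
  Segmentation never reads group labels (blinding by construction).

## Morphometric features

Per mitochondrion (names are the assay's feature labels; "volume"
means 2D pixel area, units px):

* `MitoVolume` — component pixel count.
* `MitoErosionBodies` / `MitoPerimeter` — erosion with a radius-1 disk
  (3×3 cross); surviving pixels are the bodies (count = connected
  components), and the removed rim is the perimeter (pixel count).
  `perimeter + body pixels = area` holds exactly.
* `MitoSkel` — pixel count of the thinning skeleton
  (`skimage.morphology.skeletonize`); topology (component and cycle
  counts) is preserved, verified against an Euler-characteristic oracle.
* `MitoNodes` / `MitoEndpoints` / `MitoNodeDegree` — skeleton pixels
  with ≥3 / exactly 1 8-neighbours; node degree is the mean neighbour
  count over node pixels, 0 for node-free skeletons (documented choice;
  a graph-theoretic mean degree would be a reasonable alternative).
* `MitoFormFactor` — perimeter²/(4π·area) with the subtraction-defined
  pixel-count perimeter. Because this perimeter is a pixel count, not a
  contour-length estimate, the form factor of a digital disk is ≈0.8
  rather than 1; the feature is used comparatively, where the constant
  convention cancels.
* `MitoAspectRatio` — major/minor axis of the moments-fitted ellipse,
  minor axis floored at 1 px (a digital object is at least one pixel
  wide; a 1-px component has ratio 1).
* `TMRM_MitoMask` / `TMRM_Cell` — mean TMRM intensity over the union of
  a cell's mitochondrial pixels / over the whole cell area. Background
  subtraction is not applied by default.

Per-mito features are averaged per cell as **unweighted** means; cells
with zero mitochondria keep cell-shape features but are excluded from
per-mito means (logged). Subjects are unweighted means over cells;
subjects with fewer than 175 analysed cells are flagged.

## Statistics

Two-group comparisons choose the test from the data's shape:
Shapiro–Wilk normality per group at α = 0.05 (both must pass) →
Welch t; otherwise two symmetry tests per group — asymmetric if either
rejects in either sample — → Mann–Whitney U when symmetric, else a
permutation test on the mean difference. The permutation test uses
full enumeration when the number of group assignments is ≤10⁶ and
otherwise Monte-Carlo with the add-one convention
p = (1+hits)/(1+n_perm); the full-scale default is 10⁷ permutations,
scaled to 10⁵ in the pipeline default for desk-scale runs. Families of
tests are Bonferroni corrected (p·m capped at 1).

The symmetry tests studentize the mean–median distance: the
Cabilio–Masaro statistic √n(x̄−med)/s with its normal-law asymptotic
variance 0.5708, and Mira's statistic based on the Bonferroni measure
2(x̄−med) with a distribution-free plug-in variance
4[s² + 1/(4f̂²) − MAD_med/f̂], where f̂ is a Gaussian-KDE estimate of
the density at the median corrected for kernel smoothing by the
normal-reference factor √(1+h²/s²) (without it the peak density is
underestimated and the test is conservative). Both tests hold 4–6.5%
empirical size at n = 100 under a Gaussian null and have essentially
unit power against exponential skew at n = 200.

Fisher's exact test (two-sided, sum of hypergeometric probabilities at
most that of the observed table) is computed by exact integer
enumeration, so tied tables are handled without floating-point
ambiguity; a zero margin returns p = 1 by convention. Pearson
correlations are categorised negligible (<0.30), low (<0.50), moderate
(<0.70), high; the correlation matrix is ordered by average-linkage
hierarchical clustering on Euclidean distances between correlation
vectors. The membrane-potential regression is OLS of TMRM on
MitoVolumeMean, MitoSkel, MitoEndpoints, MitoNodeDegree plus diagnosis
(0/1, case = 1), age, and gender (0/1, male = 1; reference female) with
an intercept; rank-deficient designs fail loudly naming the collinear
columns. Note that when fitted on pooled single-cell records the
standard errors ignore within-subject correlation — the same caveat
applies to pooled single-cell histogram comparisons.

Doubling time between passages is Δt·ln2/ln(n₁/n₀) days; no growth
(n₁ ≤ n₀) is flagged undefined (NaN), never returned negative.

## Classification

Linear-kernel SVM, C = 1, features z-scored inside each training fold,
leave-one-subject-out cross-validation, held-out decision scores
pooled into a single ROC; AUC by trapezoid, cross-checked against the
Mann–Whitney identity U/(n₊n₋) to machine precision. Class weights are
balanced because leave-one-out always unbalances the training classes,
which otherwise biases the pooled null AUC visibly below 0.5 at
n = 40. The CV scheme and kernel are the smallest-assumption defaults
for a ~60-subject cohort; both are configurable. Two feature modes are
compared: baseline features only, and baseline + FCCP blocks
concatenated per subject.

## Synthetic data

No study images are publicly available, so every stage is validated on
a simulator with pixel-exact ground truth.

**Rendered tiles.** Cells sit on a jittered grid (no overlap by
construction; an explicit `touching_pairs` option renders overlapping
cell pairs for splitting tests, with the pair identities recorded in
the ground truth). Nuclei are filled ellipses (radius 15 ± 2 px),
cells disks of radius 52 ± 4 px with a radially decaying CellMask
profile (bright near the nucleus), background 80 intensity units
(just below the fixed >100 nucleus threshold, so the threshold remains
meaningful under noise), Gaussian read noise σ = 20, 16-bit output.
Mitochondria are random trees: a Galton–Watson process in which each
segment (compass-direction polyline, length ~N(10, 3²) px) branches
into two children with probability 0.3, capped at 7 segments per tree.
Trees are rasterized 1 px wide and optionally dilated to 3 px (the
default; TMRM is rendered with a bright centerline and a 0.55× flank
so the DoG edge is sharp). The grower rejects any geometry that would
violate clean 8-connected topology — every junction pixel has exactly
three neighbours, every tip one — so generative branch and endpoint
counts are *exact* pixel-level truth, not approximations. Collision
avoidance keeps distinct mitochondria ≥2 px apart after dilation.

**Structure-level cohorts.** For cohort-scale experiments the same
generative law is sampled without rasterization (vectorized over all
mitochondria of a subject): segment counts from the capped
Galton–Watson recursion, skeleton length ~N(S·λ, S·σ²), area =
skeleton × width factor (width 1 or 3 with equal probability — the
width variation decorrelates volume from skeleton length and makes
the regression identifiable), endpoints = branches + 2, node degree 3
for branched trees. This route generates a 40-subject × 200-cell ×
2-condition cohort in under a second. The rendered and structural
routes share parameters but are not identical in law: rendered trees
are truncated by collisions, so their size distribution is shifted
slightly downward. Contracts that need pixel truth (segmentation
recovery, skeleton topology) use rendered tiles; cohort-statistical
contracts use the structural sampler.

**Group effect (the "case" condition).** Defaults encode the disease
signature: mitochondrial count ×1.4; segment-length multiplier set
*analytically* so that expected total mitochondrial mass per cell is
group-invariant (fragmentation without mass change) given the count
effect and the branching effect's impact on expected segment number;
branch probability ×0.6 (reduced branching); TMRM retention under
FCCP ×1.5 (resistance to depolarization); basal TMRM ×1.03 (modest
hyperpolarization: detectable in pooled single-cell analysis, marginal
at the subject level with 20 + 20 subjects). Per-subject lognormal
random effects (σ = 0.05) on count, size and TMRM create realistic
between-subject variance; ages ~N(66, 6²) years, gender frequencies
follow the motivating cohort's imbalance, doubling times are lognormal
with case medians ≈16 d vs control ≈4.9 d (slower growth in cases).
Membrane potential is linearly coupled to morphology (positive in
mean volume and endpoints, negative in skeleton size and node degree)
with coefficients chosen so morphology explains a substantial share of
TMRM variance, mirroring the strongly significant regression the assay
is built around.

**What the simulator does not emulate:** optical realism (PSF,
photobleaching, spectral bleed-through), 3D structure, illumination
gradients, cell-shape heterogeneity beyond ellipses/disks, mitophagy
dynamics, or temporal change. Passing tests therefore demonstrate the
pipeline's correctness on geometry and statistics it was designed for,
not robustness to every artefact of real microscopy.

## Numerical and scale choices

* Connectivity is 8-connected everywhere (preserves thin diagonal
  branches).
* All randomness flows from explicit seeds; every stage is
  byte-reproducible for fixed inputs and config.
* Test-suite problem sizes: one 20-cell tile for segmentation recovery,
  25 tiles (100 pairs) for splitting, ~500 fixtures for skeleton
  topology, 2,000 replicates at n = 100/100 for test calibration
  (permutation at 10⁴ resamples), 20-replicate 20 + 20 × 200-cell
  cohorts for effect-direction, regression-sign and classification
  checks, 50 replicates for the null-AUC band. These sizes give stable
  Monte-Carlo bands while keeping the default suite desk-scale.
* The Fisher sweep in the tests enumerates every 2×2 table with
  N ≤ 40 against an exact-rational oracle.

## Known limitations

* The erosion-based splitter assumes an intensity dip between touching
  cells; uniform-intensity slabs with multiple nuclei are flagged, not
  split.
* The auto DoG threshold presumes foreground sparsity (≲1% of pixels);
  dense mitochondrial carpets would need a fixed threshold.
* Exact Mann–Whitney p-values are only used for min(n) ≤ 8 without
  ties; elsewhere the tie-corrected normal approximation applies.
* Subject-level inference treats subjects as independent; the
  single-cell pooled analyses ignore within-subject correlation (by
  design, mirroring the assay's convention, and flagged above).
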