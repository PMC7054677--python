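# Methods

`plaquekit` re-implements, as a tested library, an automated quantification
workflow for amyloid pathology in multichannel fluorescence sections of
mouse cortex: plaque and nucleus segmentation, per-cell measurements of
plaque-associated microglia, stained-area-fraction analysis with image QC,
design-based stereological estimators, and the group-comparison statistics,
together with a synthetic-image generator that makes the whole analysis
exercisable at desk scale without animal data.

## Image model and conventions

A section is a set of named 2D channels (DAPI, 4G8, Iba1, Clec7a, BACE1,
pFTAA) with a physical pixel size in µm. The pixel at array index
`(row, col)` has its centre at `(x, y) = (col·px, row·px)`. Confocal
z-stacks are reduced by per-channel maximum projection before any
quantification. Intensities are treated as real-valued and are never
rescaled: every operator used downstream (Otsu thresholding, mean
intensities, stained fractions with matched thresholds) is covariant under
a global intensity scale, so no normalisation is assumed. All physical
parameters (blur scales, areas, radii, sampling frames) are given in µm and
converted to pixels at run time, which makes the pipeline
resolution-independent.

## Segmentation

Nuclei: Gaussian blur of DAPI at σ = 0.72 µm → Otsu binarisation →
Euclidean distance map → watershed split of touching objects. Plaques:
Gaussian blur of 4G8 at σ = 7.2 µm → Otsu → 8-connected components →
discard every object with area ≤ 720 µm² (a strict `>`; an object of
exactly 720 µm² is discarded).

Otsu's threshold is computed by exhaustive search over candidate thresholds
(bin values for images, the distinct observed values for per-cell
expression vectors), maximising the between-class variance
`w0·w1·(µ0−µ1)²`. Ties resolve to the lowest threshold, and foreground is
strictly above the threshold, so a constant input yields an empty
foreground. These conventions make the operator exactly testable against a
brute-force search.

Details the operator chain leaves open, fixed here for reproducibility:
component connectivity is 8-neighbour; watershed seeds are local maxima of
the distance map with a minimum separation of `2·σ_nucleus`, and any
foreground component left seedless keeps one seed at its distance maximum
(the watershed can therefore split but never merge components); labels are
numbered by raster order of each region's first pixel.

A known property of the plaque chain: with σ = 7.2 µm blur, the
intensity-transition annulus around a plaque of radius ~20 µm carries more
histogram mass than the plaque interior, which places the Otsu threshold
well below the half-maximum crossing and inflates single-object areas by
roughly 15–25%. The effect shrinks with σ/r (≈0.4% at σ = 2 µm for
r = 20 µm; see the area-recovery unit test) and largely cancels in
group-wise burden *ratios*, which is what the group comparisons consume.

## Per-cell quantification

A cell's expression of a marker is the mean intensity over its segmented
nuclear region. Cells are classified Iba1-positive/negative by Otsu's
method on the per-cell means within one image (all-identical values give
all-negative); only Iba1-positive cells enter downstream analyses. Each
cell's distance to the nearest plaque is the Euclidean distance from the
nucleus centre of mass to the nearest plaque border pixel (border = plaque
pixel with a background 4-neighbour), zero inside a plaque; cells within
30 µm (inclusive) of a border are plaque-associated. The per-image
normalised microglia count divides each associated Iba1-positive cell by
the area of its own nearest plaque and sums (cells per µm² of plaque).

Radial intensity profiles are per-channel annulus means around the nucleus
centre of mass (default Δr = 0.5 µm to r_max = 20 µm; both are
configuration — the underlying studies do not state a bin geometry).
Annuli without pixels are NaN. Normalisation divides a curve by its own
integral (Σ value·Δr = 1 within 1e-9); Clec7a intensity histograms are
binned image-wise over fixed edges (default 20 bins over 0–300) and
normalised the same way.

Pooling is hierarchical and is the package's only inference unit
convention: image values → per-animal median (element-wise for curves) →
per-group mean ± SEM with n = animals, never n = images.

## Stained-fraction analysis (BACE1/4G8, pFTAA)

Each analysed channel is converted to a contrast-stretched greyscale (a
linear map of the 0.35th/99.65th percentiles onto 0–255, clipped; lossless,
replacing a legacy JPEG batch conversion whose compression added noise but
no method). One fixed threshold per channel is fitted for the whole run:
pooled pixel mean + k·SD over all images of that channel (k = 2 by
default, recorded in the output provenance). An image's stained fraction is
the proportion of pixels strictly above the threshold; the pipeline
computes it from 256-level histograms of the stretched greyscale, matching
the histogram-extraction route of the original workflow.

Image QC compares each image's features (per-channel mean and variance)
against (i) the other images of the same animal and (ii) the other images
of the same experimental group, using leave-one-out statistics so an
extreme image cannot mask itself. An image outside the inclusive
mean ± 2·SD band of either set on any feature is excluded. Comparison sets
smaller than 3 are skipped. The band is applied per feature with either-set
exclusion; at study-scale set sizes (≥16 images per animal) the null
false-exclusion rate of a single feature is ~7%.

The per-image BACE1 stained fraction is normalised to the 4G8 fraction of
the same image (zero-4G8 images dropped with a warning), the per-animal
median ratio is taken, and groups are compared on animal values. The pFTAA
readout applies one shared threshold inside a cortical ROI polygon and
reports the percent of ROI pixels above it.

## Stereology

Both estimators use systematic uniform random sampling (SURS): one uniform
random offset anchors a frame lattice, deterministic thereafter given the
seed.

*Cavalieri area fraction* (plaque design: 90 × 90 µm frames on a
450 × 450 µm grid, 10 µm point spacing): a point lattice with a random
sub-offset is laid inside each frame; the estimate is
100 × (points hitting mask ∧ ROI)/(points hitting ROI). Every lattice
point's marginal position is uniform, so the estimator is unbiased; on a
sampling window commensurate with the grid period the point count is
offset-independent and the unbiasedness is exact rather than asymptotic
(the calibration fixture uses a 2250 µm field = 5 grid periods).

*Fractionator density* (cell design: 75 × 75 µm frames on a 500 × 500 µm
grid): cells are counted under the unbiased counting-frame rule —
inclusion on the left/bottom edges (`x0 ≤ x`), exclusion on the right/top
forbidden edges (`x < x0 + w`) — over every lattice frame that can
intersect the ROI, so each cell is counted with probability exactly
frame-area/grid-area. Estimated population = count ÷ that areal sampling
fraction; measured volume = ROI area × a user-defined section thickness
(default 40 µm — the mounted thickness is a study input, not derivable
from 2D images, and the z-dimension deliberately collapses to this single
factor exactly as in the published population/volume readout); density is
their quotient.

## Statistics

Two-group comparisons use the two-tailed unpaired Student's t-test
(equal-variance; df = n₁+n₂−2; a Welch variant exists but is off by
default). Zero pooled variance with equal means returns p = 1 by
convention. Per-bin curve comparisons are Bonferroni-corrected by the
number of tested bins (bins with data in both groups), p_adj = min(1, m·p).
Pearson correlation reports r and the two-sided p from the t-transform on
n−2 df. Three or more groups use one-way ANOVA with Tukey HSD post hoc
p-values from the studentised-range distribution on the pooled
within-group variance. Grubbs outlier removal is iterative, two-sided,
single-outlier at α = 0.05, with critical value
((N−1)/√N)·√(t²_{α/(2N),N−2}/(N−2+t²)); iteration and sidedness are
package choices (the underlying test is stated without them). Significance
stars: * p ≤ 0.05, ** p ≤ 0.01, *** p ≤ 0.001; summaries are mean ± SEM
with SEM = sd/√n (n−1 sample sd).

## Synthetic data

The generator renders scenes with the statistical structure the analysis
assumes, with ground truth recorded before noise:

- **Plaques** are a homogeneous Poisson process (default 60 per mm²) of
  bright discs with log-normal areas (median 600 µm², σ_log = 0.5),
  lightly blurred; 25% carry a brighter compact core and are flagged as
  compact (Congo-Red-like) in truth, so compact-mask area / total plaque
  area ≈ 0.25, the diffuse/core ratio readout. The defaults give ~4%
  cortical burden in the reference (male) condition from many
  moderate-sized deposits, so a field at study age virtually never lacks a
  plaque — deliberate, because Otsu assumes a bimodal histogram and
  degrades catastrophically on plaque-free noise fields, which aged APP23
  cortex does not present. Group effects multiply the count intensity
  (defaults: female = 2.0× male; an IL12p40-knockout male arm at 0.42×
  reproduces a 58% burden reduction); a homogeneous process keeps
  estimator unbiasedness testable.
- **Cells**: nuclei are soft discs (radius 3 ± 0.3 µm) with Poisson+read
  noise giving nucleus SNR ≈ 10. Microglia (60 per mm² baseline) cluster
  near plaques: 4× density within 30 µm of a border, implemented by
  thinning so the process stays Poisson. Iba1 is an exponential halo
  (scale 2.5 µm) per microglial nucleus — the cell body fades out by
  ~6 µm. Each plaque-associated microglial cell carries an intracellular
  4G8 uptake blob (Gaussian, σ = 1.5 µm) offset 4 µm from the nucleus
  centre in a random direction, so the pooled 4G8 radial profile peaks
  near 4 µm. Clec7a expression is bimodal: activated cells (70% of
  plaque-associated, 5% elsewhere) draw from a high log-normal mode.
  BACE1 is an annular rim along plaque borders with identical per-plaque
  amplitude in every group — a built-in null for the BACE1/4G8 ratio.
- **Noise**: Poisson photon noise on signal+background, then Gaussian read
  noise (σ = 2), clipped at zero.

What the generator does **not** emulate: plaque morphology beyond discs
(no wispy diffuse deposits, no vascular amyloid), microglial morphology
(no processes — Iba1 halos are isotropic), spatial inhomogeneity of
pathology across cortical layers, staining gradients, and optical effects
(PSF anisotropy, bleaching, tiling seams). Passing tests therefore
demonstrate correctness of the measurement and inference machinery under
the stated model, not robustness to every property of real tissue.

Cohorts default to 8 animals per group and 30 images per animal (10 serial
sections × 3 regions). Per-image seeds derive from (group, animal, image)
indices via NumPy SeedSequence spawn keys, so regeneration is
bit-identical and appending images never perturbs existing ones.

## Problem sizes used by the tests and acceptance script

Chosen so a complete run fits comfortably on one CPU: the full-size
end-to-end check runs one 2× cohort at the study design (8 animals/group ×
30 images, 512×512 px); the replicate arms (power of the 2× effect,
type-I calibration of the null) run 30 and 250 reduced cohorts
(4 animals/group × 6 images, 160×160 px at 1 µm/px, with the plaque size
distribution scaled to keep ≥~8 expected plaques per field). Statistical
calibrations use 1,000 null replicates (t-test, ANOVA) and 4,000 (Grubbs);
Cavalieri calibration uses 1,000 offsets on a fixed 12% mask, the
fractionator 200 seeded Poisson fields. `scripts/acceptance.py` re-runs
the same computations at the same or slightly reduced replication and
writes each result as JSON.

## Known limitations

- Single-object plaque areas inherit the ~15–25% Otsu/blur inflation
  discussed above; burden ratios are much less affected.
- The QC exclusion proportion is data-dependent; only its contract
  (planted outliers excluded, bounded null false-exclusion, inclusive
  band) is guaranteed.
- Image-within-animal nesting is handled by median pooling, not by a
  mixed-effects model — a faithful reproduction of the source workflow,
  not a statistical recommendation.
- The fractionator has no optical (z) dissector: inputs are 2D positions
  and the section thickness enters only as a volume factor.
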