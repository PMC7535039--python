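# Methods

## Problem and model

`hetrad` analyzes intratumoral spatial heterogeneity on a pre-treatment
MRI-like volume of a tumor that later recurred in-field after
radiotherapy.  The tumor (GTV, gross tumor volume) is partitioned into
two habitats using the recurrence contour mapped back onto the
pre-treatment image: the recurrent habitat GTVr and the non-recurrent
habitat GTVnr = GTV − GTVr.  The working hypothesis is that the two
habitats differ in quantitative image texture already before treatment,
so that radiomic features could flag radio-resistant subregions as
candidates for selective dose escalation ("dose painting").

For each habitat, 47 features are computed:

* 7 first-order intensity-histogram statistics on the raw intensities:
  mean, variance, skewness, kurtosis, mean absolute deviation,
  hyperskewness, hyperflatness.  All are population moments (divide by
  N); kurtosis is the raw 4th standardized moment (Gaussian = 3), and
  hyperskewness/hyperflatness are the 5th/6th standardized central
  moments (Gaussian: 0 and 15).  These quantities are named in the
  radiomics literature but rarely defined; the standardized-moment
  reading is the one consistent with the rest of the family.
* 40 texture features on Lloyd-Max quantized gray levels: 9 GLCM
  (Haralick-style), 13 GLRLM (Galloway/Chu/Dasarathy), 13 GLSZM
  (Thibault, zone size in place of run length), 5 NGTDM (Amadasun–King).

The paired statistical stage then forms, per feature, the per-subject
difference d = value(recurrent) − value(non-recurrent); Shapiro–Wilk at
0.05 on d chooses between a paired t-test and a Wilcoxon signed-rank
test; Bonferroni at α/m (α = 0.05, m = 47, displayed as 0.001 but applied
unrounded) selects the significant features; Pearson correlations of the
paired differences and a PCA of the pooled 2n region vectors summarize
them.

## Texture conventions

All four matrix families use the 3D "merged direction" convention: the 13
unique voxel offsets at Chebyshev distance 1 are accumulated into a
single matrix per family; the GLCM is symmetric (both orderings counted)
and normalized to a joint probability; runs and zones are broken by the
ROI mask; zones use 26-connectivity.  Texture is computed on the voxel
grid, ignoring the physical anisotropy of the 0.7 × 0.7 × 5 mm spacing —
the convention of the classic 3D texture toolboxes.  An isotropic
resampling option is a possible extension, not implemented.

Normalization details that differ across the literature and are fixed
here:

* GLRLM run percentage divides the run count by (voxels × directions), so
  an ROI in which every run has length 1 scores exactly 1 regardless of
  how many directions are merged.  GLSZM zone percentage divides zones by
  voxels (zones are direction-free).
* GLCM "variation" is the GLCM variance Σ(i−μ)²P(i,j) with μ the marginal
  mean; sum average is Σ(i+j)P.
* NGTDM features use ε = 1e-6 in the denominators that can vanish
  (coarseness, strength); a constant ROI therefore has coarseness 1e6 and
  busyness/contrast/complexity/strength 0.  ε is recorded in the run
  report.
* GLCM correlation is undefined (NaN, with a recorded reason) when a
  marginal standard deviation is zero; the same mechanism flags the
  standardized moments of a constant ROI.

Matrix columns are trimmed to the largest observed run/zone size, which
changes nothing numerically.

## Gray-level discretization

Each habitat is quantized independently to Ng = 256 levels (the dynamic
range of the source images) with a Lloyd-Max scalar quantizer: alternate
"centroid = conditional mean of the cell" and "boundary = midpoint of
adjacent centroids" until the largest centroid move is below 1e-8 or 500
iterations.  If the ROI has at most Ng distinct values, the exact
zero-error codebook is returned.  Cells that empty during iteration are
re-seeded by interpolating between occupied neighbours, keeping the
codebook size fixed at Ng.

Initialization is deterministic and dual: the iteration is run once from
Ng equally spaced sample quantiles (robust for skewed intensity
histograms) and once from the equal-width grid, keeping the fixed point
with the lower MSE.  The second start matters: on lumpy empirical
distributions (spatially correlated fields produce multimodal intensity
histograms) the quantile start can converge to a local fixed point that
is worse than the naive equal-width quantizer, whereas the first Lloyd
update from the equal-width grid already weakly improves on that
baseline, so the returned quantizer provably never loses to it.

Shared-scale habitat histograms (for display and comparison) use bin
edges spanning the union of both habitats' ranges and are normalized to
relative frequencies; the default bin count is 64.  A constant joint
intensity collapses to a single flagged bin.

## Habitat partition and the in-field rule

GTVnr is the voxelwise set difference GTV − GTVr.  GTVr voxels outside
the GTV are clipped into the recurrent habitat with a warning rather than
rejected: the recurrence contour is drawn on a different scan and copied
over, so small excursions are expected.  A recurrence is classified
in-field when at least 95% (inclusive) of GTVr lies inside the 95%
isodose mask.  Out-of-field subjects are warned about but analyzed unless
strict mode (`require_infield`) is enabled; subjects with an empty
habitat or fewer than 8 voxels in either habitat are excluded and listed
in the run report.

## Statistical stage

* Wilcoxon signed-rank: zero differences are dropped; the exact null
  distribution is used for n ≤ 25 without ties in |d|, otherwise the
  normal approximation with continuity correction and average ranks.
* The paired t-test p-value equals the closed form
  2·F_t(−|mean/(sd/√n)|; n−1), which the tests verify to 1e-12.
* Zero-variance difference columns are flagged degenerate (no test is
  possible) and never counted as significant.
* Correlation p-values are unadjusted, masked at 0.05, matching the
  conventional correlation-heatmap display.
* PCA: features are z-scored before the eigendecomposition because the 47
  features span many orders of magnitude; input rows are the 2n pooled
  region vectors (n recurrent + n non-recurrent); components are ordered
  by explained variance with the sign convention that each component's
  largest-magnitude loading is positive.  The PC1 silhouette of the
  recurrent/non-recurrent labels is reported as a separation diagnostic.
* If no feature survives Bonferroni, correlation/PCA fall back to the
  top-7 features by p-value with an explicit warning.

## Synthetic phantom

The phantom generator defines the study conditions under which the
pipeline is exercised: 14 subjects, grid 64 × 64 × 12 voxels at
0.7 × 0.7 × 5 mm (spacing as acquired clinically; grid reduced from
512 × 512 × Z for desk-scale runs), an ellipsoidal tumor of in-plane
semi-axis 12 voxels (z semi-axis scaled to keep the tumor roughly
isotropic in mm, ≈ 1800 voxels), and a connected recurrent blob of 30% of
the tumor grown as the nearest-k voxels around an interior seed (convexity
of the ellipsoid guarantees connectedness and an exact voxel fraction).

Texture is a Gaussian random field per habitat: white noise of standard
deviation `noise_sd` (default 120) smoothed with a Gaussian kernel of the
habitat's correlation length, plus a habitat intensity offset
(`intensity_shift`, default +50 in the recurrent habitat) on a tumor
plateau of 1200 over a background of 600, clipped to the scanner-style
range [0, 4095] (clipping is negligible at defaults).  The noise is not
re-normalized after smoothing, so a longer correlation length lowers the
marginal variance as well as the voxel-scale roughness.  The recurrent
habitat uses correlation length 2.0 voxels vs 0.8 for the non-recurrent
habitat, making it smoother/coarser at the voxel scale: lower NGTDM
busyness and intensity variance, higher coarseness and strength — the
sign pattern the paired analysis is designed to detect.  A per-subject
global intensity offset (±50) emulates session-level scanner variation
and cancels in the paired design.  Defaults were chosen once so a
14-subject cohort detects the contrast; no quantitative effect size is
available from clinical data, so these are free parameters of the
phantom, not estimates.

The 95%-isodose surrogate is the GTV dilated by two voxels; when
`infield_overlap < 1`, the requested fraction of GTVr voxels (a spatially
coherent cap) is carved out of it.

What the phantom does not emulate: MRI physics (bias fields, coil
profiles, partial volume), lesion growth, inter-subject anatomical
variability, registration error between the diagnosis and recurrence
scans.  Passing tests therefore demonstrate that the pipeline detects a
controlled texture contrast at the study's sample size — not that
clinical recurrent habitats carry such a contrast.

## Problem sizes and determinism

Test and acceptance runs use the desk-scale grid above: one 14-subject
cohort extracts and tests in ≈ 1 s; the effect-recovery study uses 50
cohorts; the null calibration uses 1000 simulated 14 × 47 difference
tables.  All randomness flows from explicit seeds through
`numpy.random.default_rng`; phantom volumes are written as uncompressed
NIfTI-1 so repeated runs are byte-identical.

## Known limitations

* Per-habitat (not whole-image) quantizer codebooks; the alternative is a
  config flip away conceptually but not exposed yet.
* Run/zone normalization constants differ across literature variants;
  absolute magnitudes of GLRLM/GLSZM features are comparable only within
  this package's conventions.
* The family-wise error bound leans on Bonferroni and the discreteness of
  the exact Wilcoxon null; correlated features make it conservative, not
  anti-conservative.
* No isotropic resampling, wavelet-filtered feature classes, or 2D
  slice-wise variants.
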