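# Methods

This note documents the models, conventions, numerical choices and known
limitations of the iCAT reconstruction pipeline, in the order the stages
run. It describes what the code does and why; every number quoted here is
either a default the code sets or a quantity the tests and the acceptance
script compute themselves.

## Coordinate conventions

Coordinates are 0-based with pixel centers at integer positions, x to the
right and y down. Stage μm axes are taken parallel to the image axes. The
**world frame of each section is the high-magnification EM pixel grid at
5 nm px⁻¹**; every tile (FM at ~80 nm px⁻¹ in the synthetic presets, EM-low
at 38 nm px⁻¹, EM-high at 5 nm px⁻¹) carries one invertible 2D affine
transform into that frame, applied to column points as p′ = A p + t and
serialized row-major as `[a11, a12, tx, a21, a22, ty]`. Section thickness is
fixed at 100 nm and only enters as z-spacing metadata in exports.

Composite rendering uses painter's order (last tile wins) with
inverse-transform bilinear sampling and zeros where no tile reaches. No
feather blending: the contract stays deterministic, and blending would only
cosmetically hide stitching error that the residual reports quantify.

## Section detection

The slide overview (~7 μm px⁻¹) is processed in a fixed order: percentile
contrast stretch (1st–99th) with a light σ = 1 px Gaussian denoise,
grayscale conversion, Otsu threshold to a binary section mask, Sobel
gradient magnitude of the masked grayscale, marker seeding, and
marker-controlled watershed (4-connectivity) with one extra background
marker; basins are finally clipped to the mask so boxes stay tight.

Automatic marker seeding places one marker per expected section at deep
gradient minima: candidates are in-mask pixels in the lowest gradient
quartile (with a small absolute tolerance, because the gradient of a flat
plateau is float noise of order 1e-17 rather than exactly zero), ranked by
Euclidean distance from the mask boundary, and selected greedily under a
minimum pairwise separation (default ≈ half the expected section diameter,
√(mask area / n) / 2). The boundary-distance ranking is what breaks the ties
that uniform section interiors otherwise produce; it also makes the seeding
robust to σ = 5 gray-level noise (verified in the tests). A user-supplied
marker list overrides the automatic seeding, since some slide layouts will
defeat any automatic rule.

## Cross-modal (CL-spot) registration

Spot localization estimates the background by 3-round sigma clipping,
detects local maxima above mean + 5σ, and refines each to sub-pixel
precision with an isotropic 2D Gaussian fit in a 7×7 window
(amplitude, center, σ, offset; bounded Levenberg–Marquardt); a
background-subtracted intensity-weighted centroid is the fallback when the
fit fails. The isotropic-PSF assumption is a deliberate simplification —
real CL spots inherit camera and optics distortions that this package does
not model (see Limitations).

Grid matching normalizes both point sets by centroid and RMS radius, then
scores candidate rotations: the principal-axis difference with its 90°
multiples, plus a coarse 15° sweep. Each candidate is paired by mutual
nearest neighbors with rejection beyond 0.25 × grid pitch and then
*refined* — an affine fit to the accepted pairs re-maps the spots and the
pairing repeats (two rounds). Refinement matters twice over: a pure
rotation pre-alignment leaves corner spots of larger grids outside the
rejection radius, and a square grid has accidental diagonal pseudo-
alignments whose raw inlier counts can beat the true rotation but which
collapse when refined. Among refined candidates of equal support the
smallest rotation wins: a symmetric grid is genuinely 4-fold ambiguous, and
the tie-break encodes the physical prior that the FM–EM mounting rotation
is modest.

The affine fit itself is closed-form weighted linear least squares over the
six coefficients; fewer than three pairs or collinear support raises an
error rather than returning a degenerate transform. Only affine models are
fitted — field-distortion correction beyond affine is out of scope.

## Feature extraction and matching

SIFT (scikit-image implementation) provides keypoints and descriptors.
Initial 2× upsampling is enabled automatically for images smaller than
150 px on a side — the downscaled low-magnification views are otherwise too
feature-poor — and disabled for larger tiles where scale-space
interpolation already yields sub-pixel keypoints at a quarter of the cost.

Matching applies Lowe's ratio test (0.8) with cross-checking, then RANSAC
under the montage transform model: a one-sample translation hypothesis with
3 px inlier radius and refit for translation, scikit-image's RANSAC with
similarity/affine models otherwise (1000 trials, fixed seed 1234, all
configurable). A consensus below three inliers — or below twice the minimal
sample for the rigid/affine models, since a minimal-sample model fits its
own support exactly — is returned empty: tiny consensus sets between
unrelated textures are indistinguishable from chance.

## Global alignment solver

Both the 2D montage and the 3D volume solve are instances of one sparse
linear least-squares problem over per-tile transforms:

    min Σ_matches Σ_i w_i ‖T_a p_i − T_b q_i‖² + λ Σ_tiles ‖T − T_init‖²_F

with one anchor tile (lexicographically smallest id by default) frozen at
its initial transform to fix the gauge. Three per-tile models are
available: `translation` (2 unknowns, linear part frozen at T_init — the
default for montages, which an ultramicrotome nominally produces
translation-only), `rigid` (a linearized similarity, 4 unknowns), and
`affine` (6 unknowns, used for cross-modal/3D stages where sections rotate
and shear on pickup). All are linear in their unknowns, so the optimum is a
single sparse normal-equations solve (`spsolve`; LSMR optionally for very
large systems). λ defaults to 0.005 per match-point-equivalent — small
enough not to bias sub-pixel recovery, large enough to keep weakly
constrained tiles near their stage positions.

Unknown translations are parameterized as the world position of the *tile
center* rather than of the pixel origin. This is a conditioning choice:
with raw pixel coordinates (hundreds of pixels) the normal equations square
an already large column imbalance, and the affine solve visibly fails to
reach its optimum; centered coordinates keep the system well conditioned.
It also makes the λ-regularizer penalize center drift, which is the
physically meaningful quantity. Test oracles (brute-force dense
normal-equations assemblies) agree with the sparse solver coefficient-wise
below 1e-8 for all three models.

A disconnected match graph is an error that lists the components — for the
volume solve, the weakly connected *section groups*, with the advice to
raise the depth-search window, since that is the mitigation the workflow
intends.

## Cross-spatial registration and overlay

Each low-mag EM tile is registered against a composite of the high-mag
tiles its stage footprint overlaps, rendered at the low-mag pixel scale
(rescaling the fine montage down, rather than the coarse tile up, keeps
feature scales comparable). Feature matching uses the affine RANSAC path;
the fit plus the composite's placement gives T_emlow→world. The linear
part's singular values are asserted within ±5% of the nominal pixel-size
ratio 38/5 = 7.6 — a recovered scale outside that band means the
registration latched onto a false consensus and is reported as a failure
instead of silently producing a warped overlay.

The FM overlay is then pure bookkeeping: T_fm→world =
T_emlow→world ∘ T_fm→emlow. Overlay accuracy is bounded below by the
low-mag pixel (38 nm), and degrades where the FM field extends beyond the
low-mag footprint and the transform extrapolates; the per-tile
`extrapolated_fraction` in the QC report quantifies how much of each FM
tile is in that regime. Manual landmark correction of gap regions is out of
scope. FM tiles are overlaid independently; FM–FM overlap is resolved at
render time by painter's order.

## 3D alignment

The rough pass renders each section's montage at a downsampled scale
(default factor 16 for production-sized montages; the pipeline clamps the
factor so renders keep ≥ ~128 px of detail on the scaled-down synthetic
data), registers each section to its nearest preceding present section by
SIFT + affine fit, and chains the results. Full affine is used per section
because sections may rotate on pickup.

The depth-search plan enumerates section pairs (za, zb), 0 < zb − za ≤ d,
over the present indices; d defaults to 2 and `auto_depth` raises it to the
minimal value that reconnects the graph (the largest index jump between
consecutive present sections). Inter-section candidate tile pairs are
pruned by rough-aligned proximity (centers within 2× the tile field), then
matched with the cached stitching features. The rough alignment then acts
as a sanity gate on the matches themselves: pairs are mapped to the
rough-aligned world frame, pairs deviating > 5 px from the set's median
displacement are dropped, and sets whose median displacement exceeds 20 px
are rejected outright. This gate exists because an affine RANSAC consensus
over a small diagonal overlap can be geometrically degenerate and admit
matches hundreds of pixels wrong; without the gate a handful of such sets
measurably shears the global solve.

The fine solve then couples everything: intra-section (montage) matches,
inter-section matches at half weight (sections are decorrelated by cutting,
so their correspondences are intrinsically noisier; the 0.5 factor is a
default, not a fitted constant), λ-regularization toward the montage
solution composed with the rough transform, and the first section's anchor
tile as gauge. The solve is per-tile, which strictly generalizes a
per-section alignment.

## Synthetic data

The generators emulate the study conditions at desk scale: EM-high
5 nm px⁻¹, EM-low 38 nm px⁻¹ (ratio 7.6), FM 16× coarser than EM-high,
overview rasters standing in for the ~7 μm px⁻¹ slide camera; 12.5%
high-mag tile overlap (the acquisition protocol specifies 10–15%), 20% FM
overlap in the grid-planning math, tile-position jitter of a few pixels
hidden from the stage metadata, Gaussian sensor noise, linear shading
ramps, CL grids of 3×3 (default quarter-field pitch, clamped so border
spots stay inside the camera), serial stacks with cumulative Gaussian drift
(σ = 5 px default) and 3% decorrelation noise between consecutive sections.
The discarded-section scenario is generated as 66 cut sections with
z = 9, 10, 34 absent from the output but present in the metadata. One
global seed fans out to per-component seeds by stable CRC hashing, so
regenerating one fixture never shifts another; every generator is
bit-identical under a fixed seed.

What the synthetic data does *not* reproduce: real BSE contrast physics,
charging and beam-damage artifacts, nonlinear lens distortion, bleaching,
CL-spot PSF asymmetries, and section-to-section morphological change (the
sections share one texture plus noise, so inter-section matching is easier
than on real tissue). Passing tests therefore demonstrate the correctness
of the geometry, solvers and plumbing under controlled noise — not
field-ready robustness to every instrument artifact.

Problem sizes in the tests are chosen at desk scale as the package's own
test design: sections of 128–1024 px, 2×2 to 3×3 montages, stacks of up to
66 sections of 192 px. The solvers and store are size-agnostic.

## Pipeline

Stages run in a fixed order (simulate → segment → register-cl → stitch →
overlay → align3d → export) from a strict-keyed YAML/dict config; unknown
keys are rejected, the config is echoed into the report, and every stage is
idempotent through on-disk outputs (re-runs report "skipped (cached)"
unless forced). The stitch stage persists its matches and per-tile feature
caches so the 3D stage reuses them; the 3D stage writes its solved world
transforms to a separate `volume_transforms.json` rather than mutating the
store, so each stage's inputs remain reproducible. Any stage failure aborts
the run with the stage name and keeps partial state. ROI selection
automates fluorescence targeting (Otsu or absolute threshold, connected
components, minimum area); the report's area-reduction factor is the exact
geometric ratio of the section and ROI boxes.

## Known limitations

* Affine-only registration everywhere; no elastic deformation, no
  distortion-field correction — on real data these dominate the residual
  error budget below the tens-of-nanometers scale.
* Spot detection assumes sparse, isotropic, high-SNR CL spots; dense or
  saturated grids need different localization.
* The square CL grid is 4-fold rotationally ambiguous; the resolver prefers
  small rotations, which is only valid while the FM–EM mounting rotation is
  below ±45°.
* Section detection assumes bright sections on a darker substrate (the
  Otsu foreground); inverted-contrast slides need a user-supplied marker
  list or pre-inversion.
* The painter's-order renderer does not blend seams; it is a reconstruction
  surface, not a presentation renderer.
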