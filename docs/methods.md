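# Methods

This package reconstructs, as tested code, a non-invasive capillary
perfusion analysis for adaptive-optics scanning laser ophthalmoscopy
(AO-SLO): motion-contrast angiography computed from registered frame
sequences, and positive identification of non-perfused ("ghost")
capillaries by fusing a structural *en face* image with the flow image.
Because the corresponding clinical raw data are not publicly deposited,
a synthetic phantom generator provides the inputs with known ground
truth; the study's cohort tables, which are fully printed, ship as a
transcribed CSV fixture.

## Synthetic phantom

The phantom emulates a ~300 µm patch of inner retina sampled at
1.5 µm/px (default 192 × 192 px): a static background with a smooth
random texture (a stand-in for the retinal mosaic; amplitude 0.06 on a
0.30 background), and a sparse capillary plexus of smooth random curves
with calibers drawn from 4–8 µm. Lesion morphologies are built
geometrically: loops as closed, slightly eccentric detours 24–50 µm
across; s-shaped inflections as one full sine period of 8–14 µm lateral
amplitude over 50–80 µm; dilations as short segments at 1.5–2× the
maximum caliber; microaneurysms as near-circular bulbs 20–60 µm across
attached to a short stalk. No claim of histological realism is made —
the shapes exercise the segmentation and classification machinery on
the morphology classes of early diabetic retinopathy.

A configurable fraction of segments (default 0.2) is flagged
non-perfused. Ghost segments are rasterized at 0.7× caliber and reduced
contrast (0.35 vs 0.50 above background), making them the "abnormally
narrow hyperreflective strings" the fusion stage must find. At lumen
crossings flow wins: a pixel inside a perfused lumen belongs to the
perfused mask, so perfused ∪ ghost = vessel and perfused ∩ ghost = ∅
holds by construction.

Frame rendering: perfused lumen pixels receive an i.i.d.-per-frame,
per-pixel multiplicative modulation, uniform in 1 ± 0.5 — the simplest
mechanism by which passing erythrocytes change backscatter frame to
frame and hence produce decorrelation. The modulation depth is a free
simulation parameter (the instrument's actual lumen dynamics are not
quantified); 0.5 yields a mean lumen decorrelation of ~0.05 against a
noise floor of ~0.004, a contrast in line with the clearly visible flow
signal of the imaging regime. Eye motion is a per-frame rigid jitter
(uniform within ±3 µm by default) plus one smooth random B-spline-like
warp per frame (4 × 4 coarse lattice upsampled cubically, bounded by
2 µm); the exact sampling warp of every frame is recorded so
registration accuracy can be scored. Sensor noise is additive Gaussian
(sd 0.02), clipped at zero.

What the generator does **not** model: the optical point-spread
function, the photoreceptor mosaic, wavefront-correction residuals,
intra-frame (line-by-line) scanner motion, vessel-wall scattering, and
physiologic flow variation. Passing tests therefore demonstrate that
the algorithms recover the constructs they are defined on — not
instrument-level performance on clinical data.

## Groupwise registration

Frames are registered to a common space with a free-form deformation on
a regular cubic B-spline lattice, 48 µm control spacing in x and y
(32 px at 1.5 µm/px; conversion rounds to the nearest integer with a
floor of 4 px). The cost is the negated mean-removed normalized
cross-correlation (the quantity the "advanced normalized correlation"
metric of standard registration toolkits optimizes), plus a small L2
penalty on control displacements (weight 1e-3) that keeps the flat,
textureless parts of the cost surface from drifting. Optimization runs
coarse-to-fine over a 5-level image pyramid with up to 128 iterations
per level: a phase-correlation translation initialization (sub-pixel,
10× upsampling) absorbs the rigid jitter, then adaptive gradient
descent with an accept/reject step schedule (grow 1.2× on improvement,
halve on failure, stop below 0.02 px) refines the lattice using the
analytic NCC gradient chained through the image gradient and the sparse
B-spline basis. A random sampler evaluates cost and gradient on a fixed
25% pixel subset per level, drawn from the sampler seed, making runs
deterministic.

Template policy: the template starts as the per-pixel **median** of the
unregistered stack (robust to outlier frames), all frames are
registered to it, and the template is recomputed as the mean of the
registered stack for a second outer round. The number of outer rounds
(2) and the template construction are design choices — an
implicit-reference groupwise formulation was deliberately avoided in
favor of an auditable register-to-template loop. The cost trace keeps
the best outer round; if a round fails to improve the mean frame-to-
template cost, its transforms are discarded, so the trace is
non-increasing. Constant frames yield identity transforms with a
warning (the cost surface is flat).

Resampling outside the source domain is flagged in a validity raster,
never fabricated; all downstream averages are restricted to the
intersection of the per-frame validity masks.

**Gauge of the recovered displacements.** A groupwise common space is
defined only up to a warp: the median template sits near the median
motion offset, not at scene coordinates. Recovery error is therefore
scored gauge-invariantly — per frame, the recovered transform composed
with the recorded true warp gives a residual field, and the mean
endpoint error is taken after subtracting the per-pixel frame-mean
residual (the common-space anchor). On noiseless 256 × 256, 12-frame
stacks with jitter up to 5 px and smooth warps up to 3 px this yields a
mean endpoint error of ~0.2 px.

## Motion-contrast angiography

For frame pair (I1, I2) the per-pixel decorrelation is

    D = 1 − I1·I2 / (½·I1² + ½·I2²),

bounded in [0, 1] for nonnegative inputs, symmetric, and invariant to a
common positive rescaling; 0/0 pixels are defined as 0 (absence of
signal is not evidence of flow). Pair set: temporally adjacent pairs by
default (N−1 pairs, the established motion-contrast construction and
O(N)); all N(N−1)/2 pairs by configuration — for N = 2 the two
policies coincide. The averaged D is the perfusion image.

Noise masking: pixels whose mean image I(x,y) falls below a threshold
are set to exactly zero in D. The threshold defaults to the 10th
percentile of mean-image intensities within the validity mask —
scale-free and reproducible; Otsu and absolute alternatives are
provided and the run manifest records the value used. Whether the
original analysis fixed one threshold across the study or chose it per
image is unknown; per-image quantile is this package's choice.

## Structure/flow fusion (ghost detection)

The visual overlay that identifies ghost capillaries is made
reproducible with standard, weight-free machinery: multiscale Frangi
ridge enhancement (scales 3/6/12 µm, converted to sigmas of
scale/pitch/2), hysteresis thresholding (0.04/0.15 on the normalized
vesselness), skeletonization, and partition of the skeleton at branch
points. Terminal spurs shorter than 20 µm are pruned, but short pieces
*between* two junctions are kept — they are genuine connectors of the
plexus, and dropping them would punch holes in the skeleton. Junction
pixels are reattached to an adjacent segment so the segments exactly
partition the skeleton.

Each segment's flow_fraction is the fraction of its support pixels
(skeleton dilated by 1 px, intersected with the vessel mask) with D
strictly above the flow threshold; a segment is perfused when
flow_fraction ≥ 0.5. The flow threshold, when not given, is calibrated
on the no-flow null: median + 6·MAD of D over background (non-vessel,
unmasked) pixels. A robust location/scale estimate is used instead of
an upper quantile because the background tail can be contaminated by
residual misregistration; 6·MAD corresponds to a ≈4σ envelope under a
Gaussian null. Raising the flow threshold can only lower flow
fractions, and raising the perfused fraction can only shrink the
perfused set (both monotonicities are property-tested).

The composite view tints perfused vessel pixels magenta and
non-perfused ones gray over the structural grayscale; non-vessel pixels
are untouched. Flow above threshold at pixels with no structural
counterpart is not classified — such segments simply do not exist in
the structural segmentation — but end-to-end evaluation counts
extracted segments that overlap no ground-truth vessel as "unmatched"
and reports them.

## Cohort tallies

The packaged CSV stores one row per study eye (21 diabetic, 13
healthy), because three participants carry different retinopathy grades
in their two eyes; OU rows in external files are expanded to OD + OS on
load. Validation rejects grades outside the study range, duplicate
eyes, and lesion flags on healthy subjects. Lesion tallies count
patients in the diabetes group; eye tallies count study eyes per group
and, within the diabetes group, per grade (the per-grade counts sum to
the 21 diabetic eyes). The abstract-level count of "mild" patients does
not reconcile exactly with a per-eye reading of the participant table;
the fixture follows the participant table.

## Problem sizes and determinism

Default study sizes: 192 × 192 px phantoms, 12 frames, 20 seeds for the
ghost-detection suite and 10 for flow-contrast Monte Carlo; the
registration recovery study uses 256 × 256 px. One global seed fans out
to stage seeds by fixed offsets; identical configuration and seed
reproduce every numeric output bit-for-bit (registration uses a fixed
sampling mask per pyramid level derived from the sampler seed, and the
optimizer is deterministic accept/reject descent).

## Known limitations

- The registration engine assumes smooth inter-frame motion; it is not
  a strip-based intra-frame correction and will not undo line-level
  scanner artifacts.
- The B-spline lattice is optimized at its full-resolution spacing on
  every pyramid level (images shrink, the lattice does not); coarse
  levels are therefore over-parameterized but regularized by the
  penalty and the smooth basis.
- Segment-level evaluation scores the segments the structural
  segmentation actually extracts; a ghost vessel missed entirely by
  segmentation produces no segment and is invisible to the confusion
  matrix (none occurred across the 20-seed suite, where every extracted
  segment matched ground truth).
- The phantom's flow modulation is per-pixel i.i.d.; real erythrocyte
  passage is spatially and temporally correlated, which would lower the
  effective number of independent pairs.
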