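# Methods

This note documents the models implemented in `tracerval`, the choices made
where the design was genuinely open, and what the synthetic phantom does and
does not establish about real data.

## The phantom

The tissue model is a flat cortical slab in a 64³ grid of 0.3 mm isotropic
voxels: white matter below, a 4-voxel gray-matter ribbon above, background
air on top. The WGM interface is the set of gray-matter voxels 6-adjacent to
white matter; on the slab it is a single plane of voxels, which makes every
conservation property enumerable. An injection region (disc, radius 3.6 mm)
sits at the centre of the slab; nine projection regions (discs, radius
1.5 mm) sit on a ring 6.5 mm away. Eight regions are connected to the
injection site by white-matter bundles; the ninth is silent (no bundle,
zero axons) and serves as a false-positive probe.

Each bundle descends from the injection gray matter into the white matter,
runs at its own depth (staggered, 5–13 voxels below the interface, so deep
runs never collide), and ascends into its target region. Centerlines are
piecewise-linear paths densified and smoothed with a 1 mm moving average, so
FACT's per-transit turning angle at the corners stays far below the 70°
stop angle. Bundle cross-sections scale with axon count,
radius = max(0.32 mm, 1.0 mm·√(N/N_max)), which makes the number of
streamline-supporting voxels roughly proportional to axon count — the
mechanism by which streamline counts can track connection strength at all.
Default axon counts (15000, 6000, 2000, 800, 300, 100, 50, 20) span three
orders of magnitude, emulating the dynamic range of real tracer data.

Diffusion tensors: bundle voxels carry a prolate tensor aligned with the
local centerline tangent (eigenvalues 1.7/0.21/0.21 ×10⁻³ mm²/s, FA ≈ 0.85);
non-bundle white matter is isotropic (0.75×10⁻³ mm²/s); gray matter is
weakly prolate along the cortical normal (0.85/0.68/0.68 ×10⁻³ mm²/s,
FA ≈ 0.13 < 0.15) so that seeds placed in cortex have a defined radial
orientation. Where two bundles overlap, the bundle with the larger axon
count takes the voxel outright (winner-take-all single-tensor partial
volume). This is deliberately the crossing-fiber failure mode: a tensor
voxel represents only the dominant population, and streamlines of the
minority population are deflected or stopped.

The optional crossing specification plants a short orthogonal bar (radius
0.44 mm, half-length 0.6 mm, 30000 axons) through one bundle's subcortical
column, centred on the boundary between the first and second white-matter
layers beneath the interface. Its vertical extent covers exactly those two
layers — the depth range the d_w = 0.3/0.6 mm seed extension can reach —
and its cross-section covers the occluded column completely, so the
occlusion is total at d_w = 0 and reversible by deeper seeding.

## DWI simulation and tensor fitting

Signal: S = S₀·exp(−b gᵀDg) per voxel and acquisition, with one b = 0 image
and 31 directions (deterministic Fibonacci hemisphere) at b = 1200 s/mm².
Rician noise is the magnitude of a complex Gaussian perturbation,
|S + n₁ + i·n₂|, n ~ N(0, σ²); the default σ = S₀/25 emulates SNR ≈ 25.
Background voxels get S₀/20 so they stay noise-dominated and masked out.

Fitting is ordinary least squares on ln S (one pseudo-inverse applied to all
voxels). The signal is clamped at 10⁻⁶·S₀ before the log (the Rician floor
can reach zero); voxels with non-finite signal are dropped from the mask
with a logged count. Negative eigenvalues are retained but flagged, and
clamped at zero inside the FA formula. Principal directions get a
deterministic sign (first nonzero component nonnegative). FA of an exactly
isotropic eigenvalue triple is exactly 0; a refit from simulated signal
carries O(10⁻¹³) floating-point jitter, which the tests treat as zero at
1e-10.

Tensor reorientation under spatial maps uses preservation of principal
direction (PPD): the first eigenvector maps through the local affine and is
renormalized, the second is Gram–Schmidt-corrected, eigenvalues are kept.

## Tracking

**FACT (deterministic).** Directions are voxelwise constant and change at
voxel boundaries; propagation is bidirectional from every seed with
FA ≥ 0.1, stepping boundary-to-boundary, and stops on entering a voxel with
FA < 0.2, on a turning angle > 70°, or at the volume edge. The start
threshold below the stop threshold is the stated configuration of the
deterministic scheme and is honored literally: it only affects seeding.
Antipodal eigenvector signs are resolved per step (nonnegative dot product
with the previous direction). Termination places the final vertex *inside*
the offending voxel — at its centre for FA stops, at the half-chord point
for angle stops — so a streamline that dies in cortical gray matter or at a
crossing layer still "penetrates" that voxel for selection purposes. Without
this convention the two-region selection rule could never retain streamlines
that terminate exactly where they should (in cortex, or at an occluding
crossing), and seed-depth extension could not recover occluded pathways.

The deterministic scheme seeds the whole volume and then selects streamlines
penetrating both (i) the injection region and (ii) the interface beneath it.
With d_w > 0, both masks are thickened into the white matter by the same
d_w: the seed mask by definition, and the interface mask because the
motivation for deeper seeding — tracer and seeds effectively extending
slightly below the cortex — applies to the selection region equally. This
interaction is not specified by the deterministic tool's documentation; the
package adopts the consistent-thickening convention and tests its
consequences (false negatives from subcortical crossings are removed as d_w
grows, never added).

**Probabilistic.** Per seed voxel, `n_samples` samples (default 10000, the
reference scheme's setting; the desk-scale pipeline default is 32) start at
uniformly jittered positions and take 0.1 mm steps. The fiber-orientation
posterior of the reference implementation is replaced by a documented
sampler: the local principal direction perturbed by an isotropic transverse
Gaussian of angular scale `orientation_sigma` (default 0.15 rad), combined
predictor–corrector style ("modified Euler": mean of the directions sampled
at the current and predicted positions). A step whose cosine with the
previous direction falls below the curvature threshold (0.2) terminates the
sample. Samples stop on entering the termination mask (gray matter excluding
the injection region), at the volume edge, or after `max_steps` (600 ≙
60 mm). Samples that never visit the waypoint mask (the interface beneath
the injection, thickened by d_w) are discarded. The per-voxel output is the
number of retained-sample visits (each sample counted once per voxel),
multiplied — when distance correction is on — by the mean path length of
the retained samples. The reference tool's exact distance-correction
normalization is not published; the global-mean-length convention is used
and verified by the on/off ratio test. An optional second direction in
designated crossing voxels (taken with configurable probability) emulates
dual-population schemes.

## Histology chain

**Micrograph segmentation.** Light Gaussian presmoothing (σ = 1 px; grey
closing of raw shot noise would otherwise lift the corrected background by
its upper noise envelope), black top-hat with a separable flat square
element (half-width 15 px at 0.87 µm/px), global threshold, connected
components, shape filters. The default threshold is Otsu's, accepted only if
it clears the background median by 3 robust (MAD) noise scales — Otsu always
splits a histogram, even of pure noise, and the guard makes "no objects" a
representable outcome; a fixed threshold can be supplied instead. Shape
filters: area in [20, 5000] px² and perimeter²/area ≥ 20 (discs score ≈ 4π
regardless of size; thin fiber profiles score far higher). The published
pipeline lists the statistics but not the cutoffs; these are configuration
with the stated rationale. The boundary is a cubic spline through ordered
manual markers, rasterized to a 6 px band; interface-crossing fibers are the
objects whose masks intersect the band (logical AND), counted by full-object
centroid.

**DDMs and transfer.** Centroids are binned into a 256×256 grid
(floor(coordinate/unit), far edge clamped); counts are conserved exactly.
Transfers through deformation fields use inverse-map pull-back (Newton
inversion of the forward map with the analytic Jacobian) with bilinear
interpolation, multiplied by 1/det J of the forward map, so integrated
counts are preserved; compensation is applied at every chain step. Whether
the compensation should use the forward or inverse determinant is settled
here by the verifiable requirement that total counts are conserved. A
particle-pushing oracle (push each centroid through the forward map, re-bin)
is kept as a test-only reference; it is compared on 16×16 aggregated
regional totals because the pull-back spreads sub-cell mass bilinearly while
particle binning assigns whole cells — on the native grid the comparison
would measure interpolation grain, not mass transport.

**Interface densities.** Fiber DDMs are assigned directly to the interface
voxel in the column under each cell centre (the fiber rule: counts of
centroids *on* the boundary); soma densities are binned into the gray-matter
volume and projected to the *nearest* interface voxel (Euclidean on voxel
centres, ties to the smallest linear index). Ground-truth centroids are
placed inside their region's voxel columns with a sub-cell inset, so the
per-region interface totals equal the planted axon counts exactly before
any deformation.

**Registration.** The slicewise 2D step is a classic thin-plate spline
(affine part + r² log r radial terms, bending-energy minimizing, exact
interpolation at zero regularization, analytic Jacobian from the
coefficients). The 3D nonrigid block-to-volume step is consumed as a given
deformation field — synthesized by `make_deformation` (sum of low-frequency
sine modes, analytic Jacobian, rejected if min det ≤ 0.2) — and never
estimated. The pipeline default chains a random smooth warp with its Newton
inverse: the net map is identity (so ground truth stays aligned) while both
Jacobian compensations are exercised non-trivially.

## Statistics

Pearson and Spearman coefficients are computed from their definitions
(product-moment on values / on average ranks); p-values are two-sided via
the t transform, with an exact-permutation option for small samples (n ≤ 7
enumerates all permutations; larger uses 10⁴ seeded resamples). Zero
variance leaves a coefficient undefined: (nan, p = 1) — the convention used
for degenerate single-region voxelwise comparisons, flagged rather than
guessed. The proportionality fit is OLS with intercept; if the t-based 95%
CI of the intercept covers zero, a through-origin refit supplies the slope.
The strongest-connection Spearman defaults to the N_B > 100 rule, with a
"k largest" alternative. No multiple-testing correction is applied, matching
the comparison design this package reproduces. The seed-depth effect on
voxelwise correlations is a one-way F-test over per-region r_p grouped by
d_w. The regression is on raw counts by default (a log-scale flag exists):
the source analysis is ambiguous on this point and raw counts keep the
proportionality hypothesis literal.

## Problem sizes and determinism

The default experiment uses the 64³ phantom, full-volume FACT seeding
(~30000 streamlines), 32 probabilistic samples per seed voxel, 20 synthetic
micrographs for counting validation, 10 random fields for the conservation
ledger and 1000 replicates for correlation oracles and CI coverage; a full
`run_experiment` completes in about half a minute on one CPU. All
randomness derives from a single integer seed through hashed per-stage
seeds; two runs with the same seed produce byte-identical reports, tables
and volumes (the config echo records the output path and is excluded from
the comparison). NIfTI volumes are written uncompressed for bytewise
reproducibility.

## What passing tests do and do not show

The phantom establishes *internal validity*: when the tensor model is
correct, orientations are voxelwise-unimodal except where deliberately
crossed, the interface is geometrically simple, and registration errors are
absent by construction, then the pipeline recovers regional connectivity
essentially perfectly (r > 0.99) and degrades in the designed ways (crossing
occlusion, rank instability of weak connections, probabilistic leakage into
silent regions). Real tissue violates these premises: fanning and kissing
fibers, partial-volume mixtures everywhere, folded cortex, registration
error of order a voxel, uneven tracer uptake, and labeling efficiency below
one (the phantom treats axon counts as fully observed, since no efficiency
value is available). Passing tests therefore validate the machinery and the
statistics, not the biological accuracy of tractography; the phantom's
crossing experiment shows the *mechanism* of false negatives, not their
real-world rate.

Other known limitations: the slab has no curvature, so interface projection
and normals are not exercised on folded geometry; the probabilistic sampler
is a stand-in with a single concentration parameter, not a posterior over
fiber orientations; micrograph clutter is geometric (discs) rather than
stain-like texture; and the FSL-style second-population emulation is only
engaged in voxels the phantom itself designates as crossings.
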