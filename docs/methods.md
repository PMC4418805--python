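# Methods

This note records how each quantity is defined and computed, the defaults
and why they were chosen, what the synthetic scenes do and do not emulate,
and the numerical choices that affect results at the margin.

## Coordinate conventions

All physical coordinates are (z, y, x) in micrometers, matching array axis
order; stacks are canonicalized to (t, c, z, y, x) at read time and voxel
centers sit at `index × voxel_size`. A fiber axis carries a right-handed
frame (u, e1, e2): u is the unit tangent, e1 (the θ = 0 reference) is the
unit vector orthogonal to u closest to +y (or +x when the axis is nearly
parallel to y), e2 = u × e1. Azimuth θ = atan2(p·e2, p·e1) for the radial
offset p. The scene generator and the unwrapping module share this
convention, so synthetic azimuths and measured azimuths agree directly.

## Synthetic scenes

The generator emulates confocal stacks of cells wrapping single
microfibers: solid cylindrical fibers (membrane-dye channel) with optional
axial intervals zeroed at sharp edges (the unstained zones under tightly
attached cells); F-actin bands as shells of default thickness 0.5 μm
centered on the fiber surface — centered rather than strictly interior so
that an unwrapping shell placed exactly at the fiber radius samples the
band's peak; obliquity implemented as a constant-pitch helical drift of the
band's axial center (dθ/ds constant), which makes the angle measured in
arc-length coordinates equal the nominal obliquity for any fiber radius;
longitudinal stress fibers as thin surface lines of ~1 μm arc width; nuclei
as solid ellipsoids with arbitrary rotation.

Optics and noise: an anisotropic Gaussian PSF (default σ = 0.8 μm axial,
0.3 μm lateral — typical of a high-NA confocal at ~0.4 μm sampling),
Poisson shot noise on the scaled signal, additive Gaussian read noise
(sd 2), and a baseline of 5. With the default peak intensity of 100 this
gives SNR ≈ 10, the "moderate" operating point used by the noisy tests.
Identical (config, seed) renders are bit-identical.

What the phantoms do *not* emulate: vectorial/defocus PSF structure,
scattering depth dependence, cytoplasmic background texture, fiber
autofluorescence bleed-through, and cell-shaped actin outside the bands.
Passing recovery tests therefore demonstrates correctness of the geometry
and statistics pipeline, not robustness to every real-world artifact.

## Fiber axes and template-cylinder diameters

Fiber masks come from a per-channel threshold (Otsu by default, fixed
values for noise-free phantoms) and 26-connected labeling with a 10 μm³
minimum component volume. The center-line is the longest path through the
3D skeleton, smoothed with a cubic smoothing spline (residual budget of
about half a voxel per point), extended along its end tangents until it
leaves the mask (skeletonization retracts from tips), oriented so the
dominant end-to-end component runs positive, and resampled at 0.5 μm.
Thinning algorithms can annihilate tubes whose medial axis falls exactly
between voxel planes; when the skeleton degenerates, the center-line falls
back to centroids of 1-μm slabs along the component's principal direction.
Components with bounding-box elongation < 3 are rejected as non-fibers.

The local diameter at an axis point is the best-scoring member of a
candidate grid (default 1–20 μm in 0.5 μm steps):

    score(D) = inside_fraction(D) − λ · guard_fraction(D),   λ = 1

with a 1-μm-long coaxial template. The inside fraction alone is maximized
by any candidate at least as large as the true cross-section, so the guard
penalty (shell from D/2 to 0.75 D) is what makes the optimum interior.
Both fractions are computed analytically as volume ratios from the radial
distances of mask voxels in the 1-μm axial slab — the continuum limit of
densely voxelizing the template, and verified against a literal
sampled-template implementation in the tests. Ties go to the smaller
candidate; axis points outside the mask get an undefined (NaN) radius and
are excluded from all distribution statistics.

Attachment sites: an axis point is "at attachment" when any cell-mask voxel
(actin channel, Otsu, ≥ 50 μm³ components) lies within local radius + 2 μm
of it, evaluated via a Euclidean distance transform in μm. The 2 μm reach
reflects that cortical actin hugs the fiber surface; it is a config knob,
as is the minimum cell volume (thin synthetic bands fall under 50 μm³).

Overall vs at-attachment diameters are compared three ways: normalized
histograms on a shared 0.5 μm grid, quantile pairs at percentiles 1–99
(the Q-Q comparison; a thin-biased attachment set falls below the identity
at upper quantiles), and the two-sample KS statistic. No single scalar
"dissimilarity" is canonical for a Q-Q comparison, so both the KS statistic
and the maximum absolute quantile deviation (in μm) are reported.

## Unwrapping

For each (s, θ) bin the planar unwrap takes the maximum (default; preserves
thin rings — mean is available) of trilinearly interpolated intensities
over radii in [r_in, r_out], default [local radius, local radius + 3 μm].
The frame is parallel-transported: each e1 is the previous one minimally
rotated onto the new tangent plane, which prevents the θ origin from
spinning along curved axes. The default θ bin count makes the surface arc
per bin ≈ one in-plane voxel (n_θ = 2πr/dx), neither oversampling nor
aliasing. Samples outside the volume are masked, not zero-filled; every
downstream statistic ignores masked bins. Layered unwrapping samples single
shells at strictly increasing radii on the shared (s, θ) grid.

Trilinear interpolation smooths phantom edges by up to one bin; this is
why band-coverage checks use the half-maximum threshold on noise-free
phantoms (the half-max crossing is the unbiased edge position of a
linearly interpolated step) and why the actin-grip coverage threshold is
330° rather than a strict 360°.

## Band detection and classification

Foreground (Otsu over unmasked bins, or explicit threshold) is labeled with
8-connectivity, merging labels that touch across the θ = 0/360 seam, so an
arc crossing the origin is a single segment. Specks thinner than 2 bins in
both directions are discarded. Coverage is the union of occupied θ bins
(× bin width, capped at 360°); the arc start is the end of the largest
circular gap. Obliquity is the angle between the component's principal axis
— computed after unwrapping θ to make the arc contiguous, in arc-length
coordinates (s, θ·r) — and the transversal direction, in [0°, 90°].

Classes: LONGITUDINAL when obliquity ≥ 60° (obliquity dominates, since a
tight helix can cover 360° without being a ring); AG when coverage ≥ 330°;
CAB otherwise. Both thresholds are config parameters; 330° absorbs the 1–2
bins that interpolation and noise erode from genuinely full rings, and no
field-standard numeric criterion for "fully circumferential" exists.

Marginal prominence is the ratio of the mean intensity of transversal
(AG/CAB) segments whose axial center falls in the outer 20% of the cell
extent at either end to that of interior segments; > 1 means bands
concentrate or intensify at cell extremities. It is flagged undefined when
either group is empty. Boundary sharpness of the fiber-stain profile is the
distance between the 25% and 75% crossings around each midpoint crossing of
the 10th/90th-percentile plateau levels; a Gaussian-blurred step of sd σ
yields 1.349 σ, recovered by the tests to 4%.

## Nuclear shape

Segmentation is a deliberately simple documented pipeline — Otsu, hole
filling, distance-transform watershed (markers from smoothed-distance
maxima, fused within 3 μm so plateau ties cannot shatter a nucleus), 20 μm³
minimum — aimed at well-separated DAPI-like blobs. Roundness is ℓ₁/ℓ₃ of
the unweighted voxel cloud's principal-component standard deviations: the
standard-deviation reading makes a (4, 2, 1)-ellipsoid score 4 and scales
linearly with axis ratios; the variance reading (its square) is exposed via
`extent="var"` since either convention yields 1 for spheres. Coplanar
clouds (ℓ₃ = 0) are flagged degenerate with infinite roundness. The
roundness-vs-diameter relation is ordinary least squares with the two-sided
slope *t*-test, the diameter taken at the defined-radius axis point nearest
the nucleus centroid.

## Kinetics and qPCR

ROI tracks are per-frame means over explicit 3D masks (delineation of
regions is the caller's choice), at a default 5-min frame interval over
13 frames (a 1-hour acquisition). No photobleaching correction is applied
by default — coordinated *increases* in some regions argue against global
bleaching in this setting — but a log-linear exponential detrend is
provided. Coordination between tracks is Pearson correlation.

RCN = 2^(−ΔCq) × 100 with the reference the *median* of the four
endogenous controls' replicate-averaged Cq (replicates are averaged before
ΔCq; duplicate wells are the norm and the mean is the unbiased combiner).
The cluster differentiation index normalizes each gene's RCN to its own
baseline (percent change), then averages across the cluster's genes —
per-gene first, so high-expressing genes do not dominate — reporting
mean ± SD and n. Inter-cluster comparisons use Welch's unequal-variance
*t*-test (two-sided); with only "t-test" specified, the unequal-variance
form is the safer default. The shipped 21-gene panel groups ten
endothelial-function genes (CD31, CAV3, CDH5, CNN1, FSHR, KDR, NES, NOS3,
TEK, VWF) as Cluster 1, ten primitive/indifferent genes as Cluster 2,
MKI67 as the proliferation marker, and B2M, CAP1, GAPDH, RPL13 as
endogenous controls; any other gene → group mapping can be supplied.

## Problem sizes and limitations

Validation scenes are kept at desk scale: single-fiber stacks of roughly
40×40×100 voxels at 0.4 μm, diameter-recovery cohorts of 20 fibers spanning
2–16 μm, regression cohorts of n = 95, and Monte-Carlo checks of 1000
replicates — sizes at which every recovery property can be verified in
seconds while exercising the same code paths as full-size stacks.

Known limitations: junctions of crossing fibers are not resolved (each
fiber is unwrapped independently); band identity is not tracked across
time; nuclear segmentation is not designed for dense tissue; template
diameters are quantized to the candidate grid; amplification-efficiency
correction and dissociation-curve QC are out of scope for the qPCR module.
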