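# Methods

`lipovol` implements a desk-scale single-particle reconstruction and
analysis chain for low-density-lipoprotein (LDL)-like particles, together
with a synthetic phantom generator that stands in for micrograph data.
This note documents the models, the defaults and why they were chosen, the
numerical conventions, and the limitations a user should know about.

## The phantom model

LDL is a quasi-spherical particle (~23 nm across) with a cholesteryl-ester
(CE) core, a phospholipid surface monolayer, and a single ~550 kDa
apoB-100 protein wrapped around the shell.  Below the CE phase transition
the core packs into smectic (layered) order with ~30 Å periodicity; above
it the core is liquid-like.  The phantom encodes exactly this radial
organization and nothing finer:

- **Core** (default radius 75 Å): in *ordered* mode the lipid density is
  radially modulated, `ρ(r) = ρ_lipid · (1 + 0.5·cos(2πr/d))` with
  `d = 30 Å`, giving concentric maxima at r = 0, d, 2d; in *disordered*
  mode the core is uniform at `ρ_lipid`.  The ordered core is rescaled to
  carry exactly the disordered core's integrated mass, so downstream
  profile differences reflect organization, not amount.
- **Shell** (default thickness 25 Å): a phospholipid annulus at higher
  density than the core.
- **Protein domains** (default 4): spherical-cap patches at fixed,
  deterministic directions on the shell, mutually separated by
  lower-density gaps.  Patch density falls off smoothly from center to
  edge (1.3→0.9 × the protein level).  A continuous density field keeps
  intensity thresholds well defined (a constant-density patch would make
  mass thresholds massively tied) and is also more physical.
- **Knob**: a radial protrusion extending ~20 Å beyond the surface,
  contiguous with domain 1 — reflecting the N-terminal β-barrel being part
  of the single apoB-100 chain.  Because it is attached, the default
  4-domain phantom segments into exactly 4 connected components.
- The whole volume is smoothed with a 0.6-voxel Gaussian to keep edges
  band-limited on the grid.

**Grids.** The reconstruction-scale default is 64³ voxels at 5.0 Å/voxel
(320 Å box).  5.0 Å, rather than a finer sampling, is forced by the
padding invariant `diameter ≤ 0.8 × box extent` together with the particle
population's 250 Å upper diameter.  The analysis-scale preset is 128³ at
2.8 Å/voxel, the 2×-binned micrograph sampling at which radial profiles
are conventionally compared.  Both are configuration, not architecture:
every operation takes the grid from its inputs.

**Population.** Particle diameters follow the measured population: mean
23 nm, SD 2 nm, range 19–25 nm.  These summary statistics are mutually
inconsistent with a naively parametrized truncated normal (the range is
asymmetric about the mean, so truncation at ±[2σ, 1σ] drags the mean to
22.6 nm).  The sampler therefore solves for the latent location whose
*realized* (truncated) mean equals the reported mean; the observable
statistics, not the latent parameters, are what the generator reproduces.

**Imaging model.** Projections are plain voxel sums along the viewing axis
(trilinear interpolation), multiplied in Fourier space by the CTF

    CTF(f) = −[√(1−A²)·sin χ(f) + A·cos χ(f)],
    χ(f)   = πλΔz f² − (π/2)·Cs·λ³ f⁴,

with underfocus Δz > 0 drawn uniformly from 1.5–4.7 µm per image, 200 kV
(λ = 0.02508 Å), Cs = 2.0 mm, amplitude contrast A = 0.07 — standard
FEG-TEM values; only the functional form matters for phase flipping.
Noise is additive white Gaussian.  The default `noise_sd = 5.0` (in
projection units; the phantom projects to ~±20) is calibrated only so that
class averages at a few tens of images per class resolve the phantom
shell; the level is otherwise arbitrary and declared as such.  Background
stacks are pure noise images from the same model, one per particle image.

What the generator deliberately does **not** model: ice gradients,
beam-induced motion, detector MTF, astigmatism (micrographs showing drift
or astigmatism were discarded at the source, so the simulator need not
produce them), structured solvent noise, or molecular-detail lipid
packing.  Consequences for interpretation: tests passing on this phantom
demonstrate that the *algorithms* implement their contracts, not that the
pipeline would reach any particular resolution on real micrographs whose
noise is colored and whose particles are conformationally continuous.

## Geometry conventions

Euler angles are intrinsic ZYZ `(rot, tilt, psi)` in degrees,
`R = Rz(rot)·Ry(tilt)·Rz(psi)`.  The volume is rotated actively by `R^T`
and projected along +z, so `(rot, tilt)` select the viewing direction
(`d = R·ẑ`) and `psi` is the in-plane rotation; the image frame vectors
are the columns of R.  Arrays are indexed (z, y, x).  Interpolation is
trilinear everywhere (rotation, projection, sinograms, polar resampling);
it is the single source of geometric tolerance quoted in the tests.
Back-projection is the exact adjoint of projection up to this
interpolation (verified by dot-product tests at the 2% level on smooth
fields).

## Preprocessing

**Phase flipping** multiplies Fourier coefficients by the sign of the CTF
computed from each image's own metadata defocus (no defocus groups).  It
is an involution and preserves power spectra exactly.  No amplitude or
Wiener correction is applied anywhere.

**MDL denoising.**  The denoiser hard-thresholds detail coefficients of an
orthogonal db4 wavelet decomposition (periodized, 4 levels), choosing the
retained-coefficient count k per image by a two-part code length

    L(k) = 1.5·k·log₂N + (N/2)·log₂(RSS(k)/N),

i.e. the bits to index and encode k nonzero coefficients plus a Gaussian
code for the residual.  For pure noise the code-length penalty exceeds the
residual savings and k→0; for structured images the large coefficients
survive.  The approximation band is always kept.  This is a documented
surrogate with the same contract as information-theoretic denoisers used
on micrographs (the original method's exact transform and code are in its
own publication); the interface isolates it so a faithful port can replace
it.  Denoised images drive *only* classification and alignment decisions;
every reconstruction consumes non-denoised (phase-flipped) pixels, and a
linearity test pins that the maps scale with the raw stack, not the
denoised one.

## Classification

"Multivariate statistical analysis" is realized as: two rounds of
translational/rotational alignment to the iteratively re-estimated global
mean (rotation search step 5°, shifts within ±¼ box — the resolution of
all alignment claims), a circular mask of radius 0.45 × box, PCA (default
20 components, full SVD), and k-means with k = n_classes.  K-means is
initialized at quantiles of the leading principal axes (one restart per
axis, up to 10, best by within-class sum of squares), which makes the
partition a deterministic function of the image *set* — invariant to input
order up to relabeling — rather than of an RNG stream.  The retained
component count (20) is a free parameter exposed in the configuration.

## Orientation assignment by cross common lines

Sinogram row θ of an image is its 1-D projection onto the in-plane
direction (cos θ, sin θ) (2° grid, extended to 360° by line reversal; rows
normalized to zero mean, unit norm).  By the central-slice theorem two
projections of one volume agree along their common line
`u_ij ∝ d_i × d_j`.  The solver:

1. computes the full line-correlation table C_ij for every image pair;
2. anchors image 1 at the identity (gauge);
3. places images 2 and 3 by a joint grid search (3° step) over the one
   remaining degree of freedom each has after its common line with the
   anchor is fixed, scoring against C_23;
4. adds each further image by a 1-D search over its free angle, using its
   best-correlated oriented partner for the constraint and all oriented
   images for the score;
5. polishes every orientation by Nelder-Mead on the summed bilinear-
   interpolated pair scores (two sweeps).

The solution is defined up to a global rotation and a global hand flip —
the intrinsic ambiguities of common lines.  A degeneracy guard rejects
inputs whose line-correlation tables are flat (mean peak-above-mean
contrast < 0.005, an order of magnitude below what quasi-spherical class
averages produce): for such inputs every pair of lines "matches" and any
solution would be arbitrary.  On noiseless projections of an asymmetric
test object the solver recovers orientations to ≤ 5° (typically ≤ 1.5°)
after gauge alignment.  The simulated tilt-pair check (re-projecting at a
known ±stage tilt and comparing correlations) resolves the hand on
phantom data, mirroring the 0/4/8° tilt-series validation.

## Reconstruction and refinement

**Weighted back-projection** ramp-filters each image with |f| in its 2-D
Fourier plane (the r* weighting that compensates uneven angular sampling;
a simple ramp rather than the exact general weighting — standard WBP
practice whose constant factor cancels in every correlation- and
FSC-based measurement) and smears it along its viewing direction.  Output
is normalized by image count, making reconstruction linear in the images
— the property that the bootstrap variance module exploits.

**Refinement** iterates: project the current volume on a quasi-uniform
angular grid (default 15° at 64³; resolution claims at desk scale are
relative, not absolute); match every *denoised* image to its best
reference by FFT correlation over a polar resampling (36 in-plane steps =
10°), with a ±4 px translational refinement against the chosen reference;
rank by correlation; retain the top fraction (default 0.75, the
[0.70–0.75] operating range is enforced with a warning outside it; ties
broken by stable sort on image index); reconstruct even/odd halves of the
retained set from the *non-denoised* images; record their FSC and the
0.5-crossing resolution (linear interpolation between shells; a curve
that never crosses reports Nyquist with a flag).  The initial model comes
from common-lines angles on the class averages, low-pass filtered to 60 Å
(a starting-resolution choice; the source procedure filters but does not
state a radius).  One dataset per run — populations from different
conditions are never pooled.

A caveat specific to quasi-spherical particles: projection matching
discriminates orientations only through the weak asymmetric features
(domains, knob), so per-image assignments on LDL-like phantoms are poor
even at high SNR.  Spherically averaged quantities — radial profiles,
layer spacing, mass thresholds — are insensitive to this, which is why the
acceptance experiments measure those; full-rotation assignment accuracy is
tested on an asymmetric object instead.

## Heterogeneity treatments

**Radial-profile filtering.**  Class averages whose annular-mean profile
(2-px bins ≈ the 2×-binned comparison sampling) has Pearson correlation
< 0.2 with *every* projection of the current model are rejected together
with their member images.  Zero-variance profiles are flagged and scored
0.  A statistical note: with the ~20 profile bins available at desk scale
the null distribution of a pure-noise class's best correlation has sd
≈ 0.27, so noise classes are rejected with probability ≈ 0.72 each — the
filter is a bulk-cleaning tool, not an exact detector.  The deterministic
rejection fixture in the tests therefore uses contrast-inverted artifact
classes (anti-correlated by construction, the signature of an uncorrected
CTF sign error), and a separate statistical test covers the pure-noise
case.

**Bootstrap variance.**  With orientations fixed (selection happens after
classification and before reconstruction), n = 200 bootstrap volumes are
reconstructed from multinomial with-replacement resamples of the image
set, angles traveling with their images.  Linearity of WBP lets all 200
volumes accumulate in one pass over per-image filtered back-projections
(a counts-matrix multiply), so the cost is one back-projection per image
plus BLAS.  Voxelwise mean and unbiased (n−1) variance are computed; the
same procedure on an equal-sized background-only stack estimates the
noise-plus-alignment variance, which is subtracted and floored at zero
(the flooring is a declared choice; whether the source procedure floored
is unstated).  The background run reuses the particle run's resampling
counts — a paired, common-random-numbers design — so identical inputs
cancel exactly instead of leaving ~50% Monte-Carlo residue.  The variance
map's spatial pattern contains an unavoidable orientation-diversity term
(different projections back-project differently even without
heterogeneity); injected conformational differences must be strong
relative to it to dominate the top percentile, which the localization
tests make explicit.

## Map analysis

- **Radial profiles**: spherical-shell means at 1-voxel bins about the box
  center (particles are centered by alignment; a center-of-mass override
  exists).  Scaled mode normalizes to unit surface-peak height for
  cross-map comparison.
- **σ-thresholds**: µ + kσ over the *whole* box including solvent,
  matching how display thresholds are quoted on full maps.  If a masked-σ
  convention were intended the numbers would differ; this is flagged, not
  guessed.
- **Mass threshold**: the largest intensity t with
  `count(≥t) · voxel³ · 0.81 Da/Å³ ≥ target`; 0.81 Da/Å³ (≈1.35 g/cm³) is
  the standard globular-protein density, fixed in configuration.  The
  achieved mass is quantized by one voxel.
- **Segmentation**: 26-connected components of the supra-threshold set;
  components under 27 voxels are dropped and logged (a reproducible
  policy for "loose connection" ambiguity); survivors are relabeled by
  descending mass.  Raising the threshold can only split, shrink or
  remove segments, never merge them (tested).
- **Layer spacing**: mean peak-to-peak distance of profile maxima inside
  the core after a 3-bin moving average, with quadratic (sub-bin) peak
  interpolation; a dominant first bin counts as the r = 0 layer.  Fewer
  than two maxima → NaN with a warning.
- **Volume alignment**: exhaustive Euler-grid search with FFT translation
  at each rotation, optional mirrored search; callers low-pass filter to a
  common resolution first.

## Docking and epitope triangulation

The model is rasterized as unit-mass Gaussians with FWHM equal to the
target resolution (σ = resolution/2.355).  The map is bandpassed to
15–80 Å and thresholded at µ + 1.7σ before fitting.  Docking is an
exhaustive ZYZ-grid rotational search (default 15°; the spherical-
harmonics acceleration of fast docking tools is deliberately replaced by
brute force with the same contract) with the best translation per rotation
found by FFT cross-correlation on zero-mean fields (hence invariance to
any additive map offset).  Greedy non-maximum suppression uses a rotation
radius of 0.9 × the grid step and 3 voxels of translation: duplicates at
one grid point collapse while adjacent-grid refinements of one solution
remain visible as separate ranks — which is why a well-determined
solution shows up as two nearly tied top poses when the truth falls
between grid points.  The top 40 surviving poses form the z-score
population (fewer triggers a warning), `z = (score − mean)/sd`, one-sided
normal tail p-values; an sd of zero flags the p-values undefined.  Both
hands of the map are docked and the better-scoring hand reported.

Epitopes arrive as (latitude, longitude) on the particle sphere.  Exactly
three anchors (MB19, MB24, MB11 in the shipped fixture) are matched to 3-D
positions taken from the docked model; the best-fitting *proper* rotation
(SVD orthogonal Procrustes; a required reflection raises unless explicitly
allowed) carries all epitopes onto the surface radius.  Rotations are
isometries of the sphere, so pairwise great-circle distances are preserved
exactly.  The packaged `epitopes_synthetic.tsv` carries the real antibody
names and apoB-100 residue ranges but *placeholder* coordinates (the
measured latitude/longitude table lives in its own publication); a loader
accepts user-supplied real coordinates.

## Problem sizes of the shipped experiments

The turn-key experiments run on one CPU: layer-spacing recovery uses one
ordered-core phantom, 2000 projections, full pipeline, 2 refinement
iterations (~4 min); the core-order contrast uses matched 20-phantom
populations (identical sampled diameters, only core mode differing) × 100
projections each (~2× that); classification plumbing uses 3000 images →
50 classes (~2 min); the mass-threshold and population checks are
seconds.  These sizes are the package's defaults for a desk-scale
demonstration; all counts are arguments.

## Known limitations

- Orientation assignment on quasi-spherical particles is weakly
  determined (above); per-particle angular accuracy claims are only made
  for asymmetric objects.
- The convergence radius of ordered- vs disordered-core profile
  differences is measured against a 5%-of-peak band.  Phase flipping
  corrects CTF signs but not the low-frequency amplitude suppression, so
  the reconstruction's point-spread function has long-range oscillatory
  sidelobes (tens of Å at 4.7 µm defocus); the core-mode difference field
  is convolved with that PSF, leaking a few percent of contrast into the
  75–95 Å range.  At the default scale (2000 projections) the measured
  convergence radius therefore lands 2–4 shells (10–20 Å) outside the
  generator's 75 Å core radius, varying with seed.  Sharpening this would
  require CTF amplitude correction, which the implemented procedure
  deliberately omits (phase flipping only).
- The MDL denoiser is a surrogate for the cited method, equivalent in
  contract, not provenly in output.
- No gold-standard (independent half-set) refinement, no per-particle
  defocus refinement, no symmetry handling (LDL is asymmetric), no
  flexible fitting, and no eigenvolume/covariance heterogeneity analysis
  — all out of scope by design.
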