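# Methods

This note records the models, algorithms, parameter choices and numerical
conventions behind `kernelpheno`, and what the synthetic phantoms do and do
not establish about behaviour on real data.

## Acquisition model and preprocessing

Cubes are VNIR reflectance hypercubes (rows × cols × bands, wavelengths in
nm) read from ENVI header + raw binary files (BSQ/BIL/BIP, float32/float64/
uint16).  Radiometric calibration is R = (raw − dark)/(white − dark); the
dark reference is optional (R = raw/white without it) and the white
reference may be a full frame or a single spectrum broadcast to all pixels.
Zero denominators yield non-finite pixels that background filtering later
removes — they are not errors.

Analysis is restricted to 425–974 nm (both limits inclusive), discarding the
noisy sensor extremes.  Spectral smoothing is Savitzky–Golay with window 11
and polynomial order 2.  The nominal smoothing scale of the acquisition
protocol is a 10-band window; a symmetric SG filter needs an odd width, so
the default is the nearest odd window above it.  Edge bands are handled by
fitting the polynomial to the truncated terminal window (`mode="interp"`),
never by padding with invented data.  Reflectance is not clipped at 1:
specular values pass through and are handled by masking and unmixing.
Wavelength lookups (RGB rendering at 640/550/460 nm, the color-index bands)
always use the nearest discrete band, ties resolving to the lower
wavelength; sensors sample discrete bands, so interpolation would
manufacture data.

Background filtering removes pixels with any NaN/Inf band and pixels whose
summed absolute reflectance is ≤ 1e-12 (the kernels sit on a black,
low-reflectance platform).  Kernels are 8-connected components of at least
50 px (dust rejection; both configurable), labelled top-to-bottom then
left-to-right by centroid to match the physical grid layout.  Touching
kernels are not split: the acquisition protocol spaces kernels on a grid,
so a watershed step would only ever split real kernels.

## Spectral unmixing

The linear mixing model r ≈ E a (a ≥ 0) is solved per pixel by NNLS;
fractions are then normalized to sum to one, as stated for the original
workflow — a fully simplex-constrained least squares variant is out of
scope.  Pixels whose NNLS solution is identically zero are flagged
unclassifiable.  The reconstruction error

    rRMSE = sqrt(mean over pixels and bands of (R − E a)²) / mean(R)

uses the **pre-normalization** abundances: normalization changes the fit,
and the error must describe the least-squares solution actually computed.
Because least squares over a superset of endmember columns cannot fit
worse, rRMSE is non-increasing over nested endmember sets — a property the
tests exercise.

### Endmember extraction

All three extractors run in exactly n_em − 1 PCA dimensions.  A simplex
with n_em vertices spans n_em − 1 dimensions; fewer can hide a low-variance
vertex (a dark background cluster contributes almost nothing to total
variance yet is a true vertex) inside the projected hull, while extra
dimensions carry mostly noise that dilutes PPI purity counts.  The
standalone `pca_reduce` keeps the conventional contract (smallest dimension
reaching 99.9% cumulative explained variance) for general use.

* **PPI** projects scores onto 10⁴ random unit skewers (seeded); the
  extreme pixel at each end of every projection (both min and max by
  default) accumulates purity counts.  Candidates are ranked by count and
  greedily reduced to n_em subject to near-duplicate rejection.
* **N-FINDR** maximizes the simplex volume |det| over vertex swaps from a
  seeded random start until no swap increases the volume.  Degenerate
  (zero-volume) data return the initial set with a warning.
* **FIPPI** re-derives the skewer set each iteration from the current
  extreme pixels' score directions and stops when the extreme set
  stabilizes (≤ 20 iterations on all test scenes).

Near-duplicate rejection uses two criteria.  Spectral angle below 0.05 rad
counts as duplicate only when the two spectra also have similar brightness
(norm ratio > 0.5): spectral angle is intensity-invariant, and without the
brightness guard a dark flat background spectrum is "identical" to a bright
featureless endosperm spectrum.  Additionally, two candidates closer than
0.1× the candidate-cloud diameter in score space are treated as the same
vertex: at realistic noise levels the per-pixel noise at a dark vertex
exceeds the angle threshold even though both pixels represent the same
material.  All thresholds are configurable.

Returned endmember spectra live in the original band space, never in PCA
space.  By default each selected vertex spectrum is the mean of the purity
candidates co-located with it (within 0.05× the cloud diameter in score
space): a single extreme pixel carries the full per-band sensor noise,
which otherwise dominates the abundance error budget at 30 dB.  On
noiseless data co-located candidates are spectrally identical, so the
refinement changes nothing; `refine=False` restores the literal
single-pixel behaviour.  Endmembers are ordered by descending mean
reflectance for reproducible identities.

### Two-pass workflow

Pass 1 extracts 10 global endmembers and unmixes the full foreground.
Endmembers whose mean reflectance is below 0.5× the median of the extracted
endmembers' means **and** whose coefficient of variation across bands is
below 0.15 are flagged as background/shadow; pixels whose summed background
fraction exceeds 0.5 are removed.  The median is taken over endmember means
rather than over pixels: background pixels usually dominate the pixel
count, so a pixel-level median would collapse to the background level and
the criterion could never fire.  The CV threshold sits at 0.15 because
genuinely flat platform spectra have CV near zero while the darkest
endosperm class, which carries real spectral shape, sits near 0.2 — a 0.25
cut misclassifies it.  Pass 2 repeats extraction and unmixing on the
retained kernel pixels (default again 10 endmembers; the kernel-specific
count is an open choice and is configurable).  If no endmember qualifies as
background the pass-1 mask is kept with a warning.  Note the flatness
criterion applies to noiseless or smoothed spectra; at low SNR without
smoothing, noise inflates the CV of dark spectra and the criterion becomes
conservative.

## Vitreousness

Tissue assignment maps endmembers to {glassy, intermediate, mealy, other}.
Automatic mode considers endmembers concentrated inside kernels (mean
in-kernel fraction > mean out-of-kernel fraction) and ranks them by mean
spectrum reflectance: mealy endosperm scatters most (highest reflectance),
glassy least, so highest → mealy, lowest → glassy, the middle-ranked one →
intermediate, everything else → other.  Ties break toward the lower
endmember id and are logged.  Manual mappings are used verbatim.

Pixel classification takes the argmax over class-summed abundances
(multiple endmembers may map to one class).  A pixel whose overall argmax
endmember is mapped to "other" is left unclassified and excluded from
N_total.  The index V = (N_g + 0.5 N_i)/N_total is computed per kernel and
aggregated per cultivar as an unweighted mean ± sample sd.  The visual
reference index applies the same formula to evaluator counts of whole
kernels (glassy > 70% vitreous area, intermediate 30–70%, mealy < 30%),
with the kernel-set size (default 42) as an input.

Two class-binning conventions coexist deliberately.  Kernel classes derived
from V (`v_to_class`, used for confusion matrices) put V = 0.7 in the
glassy bin; the prediction protocol's `index_to_class` keeps 0.7 in the
intermediate bin, following the protocol's own three-class rule.  Both
boundary behaviours are fixed, documented and tested.

## Morphometrics and crease geometry

External morphology uses the equivalent-ellipse convention: GL/GW are the
major/minor axis lengths of the region's second-moment ellipse (robust to
orientation, unlike a bounding box), GA the pixel area, GP the Crofton
perimeter estimate (unbiased on smooth digitized contours; the naive
pixel-edge estimate biases circularity ~10% low), AR = GL/GW and
GC = 4π·GA/GP².  An optional mm/px scale converts units.

Cross-sections are segmented by Otsu threshold, hole filling and largest-
component selection.  Crease measurement:

1. The deficit set is the convex hull image minus the mask; the crease
   region is its largest connected component.  Components below 16 px are
   rasterization slivers, not creases — without this floor a digitized
   convex disk would report a spurious crease, and the tests require convex
   shapes to yield exactly zero.
2. A 3×3 morphological opening strips the 1-px zigzag sliver that oblique
   rasterized edges contribute before the mouth of the groove is located
   (depth and area still use the full region).
3. The opening chord lies on the hull facet breached by the region (the
   facet with the most cleaned crease pixels within 1.5 px of its line);
   the chord endpoints are the extreme cleaned pixels along that facet.
   CW is the endpoint distance + 1 px (pixel-center to pixel-extent
   conversion).
4. CD is the maximum perpendicular distance from the chord to mask pixels
   bordering the crease region — measuring to the groove's wall rather than
   to deficit pixels makes CD equal the notch depth exactly on axis-aligned
   phantoms.
5. GT and GW are the mask extents perpendicular and parallel to the chord
   (+1 px each); SA is the mask area; CA the crease-region area.

Derived indices: DR = CD/GT, WR = CW/GW, CR = CA/(SA + CA) and
CI = (CD/GT)·(CW/GW²).  CR's denominator includes CA (the whole-section
convention used in the results that report it); the alternative CA/SA is
exposed as an extra column.  CI is evaluated exactly as defined and
therefore carries units of 1/length despite being grouped with the
dimensionless indices — documented, not silently corrected.  The width in
WR/CI defaults to the cross-section's own width (crease analysis may use a
kernel set never imaged intact); an externally measured GW can be passed
instead.  Rasterization limits accuracy to about ±1 px on CD/CW, a few
percent on CA, and ~±1 px worth of relative error under rotation — the 2%
rotation-invariance check therefore runs on a 600×300 phantom where a pixel
is below 2% of every measure.

Z-score normalization and the coefficient of variation (100·sd/mean) both
use the population sd (n denominator), matching the plain formula they
implement; missing values are ignored in the moments and preserved.

## Chemometrics

SNV standardizes each spectrum to mean 0, sd 1 (population sd); constant
spectra yield NaN sentinels.  The coat-color index uses log₁₀ reflectance
floored at 1e-6.  In paired mode (spectra before and after alkaline
treatment), ΔlogR(λ) = log R_pre − log R_post and the index is
ΔlogR(700) − ΔlogR(520); with only the pre-treatment spectrum it degrades
to log R(700) − log R(520).  520 nm captures pigment absorption, 700 nm is
a structure-dominated reference.  The red/white threshold is 0.175 with
the boundary value classed red; the log base is configurable but rescales
the index and hence the threshold, so base 10 is the documented default.
The notation Δlog(R700 − R520) is read as a difference of Δlog values, not
a log of a difference: the paired construction (largest treatment contrast
at 520 nm, reference at 700 nm) only makes sense on the former reading.

PLSR uses NIPALS factor extraction with preprocessing (optional SNV on row
spectra, then column mean-centering and unit-variance scaling) applied
inside each CV split from training-fold statistics.  Folds are seeded and
stratified by response quantile (each fold spans the response range, which
stabilizes regression CV).  The latent-variable count minimizes pooled CV
RMSE, ties resolving to fewer LVs; the count is capped at the matrix rank.
VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) with
SSY_a = q_a²·t_aᵀt_a from the sequential deflation, so mean(VIP²) = 1
identically — asserted for every fitted model.

## Random-Forest protocol

A fixed configuration (100 trees, unrestricted depth, random_state 42,
5-fold seeded CV) is shared across tasks.  Training is two-step: fit on all
samples, rank by absolute in-sample prediction error, drop the top
ceil(0.05·n), refit on the remainder; the dropped ids are reported.
In-sample RF errors are optimistic, but a sample ten standard deviations
off still averages predictions from the ~37% of trees that never saw it,
so gross outliers surface reliably; an out-of-bag error mode is available.
Vitreousness predictions are inverted (ŷ ← 1 − ŷ, because the driving
abundances track mealy tissue) and then min–max scaled per prediction batch
into [0.1, 0.9]; a constant batch maps to 0.5 with a warning.  Scaling is
batch-dependent by construction — documented, as single-sample prediction
is not meaningful under it.  CV is evaluated on the untrimmed data (the
trimmed final model is reported separately; the ordering of trimming and
CV is not fixed by the protocol, so both numbers are emitted).  R² is
computed on pooled out-of-fold predictions; per-fold values are tabulated.

## Synthetic phantoms

The generators are first-class, tested code and the package's verification
substrate.

**Kernel scenes** place elliptical kernels on a grid (defaults: 12×8 layout,
512×512 frame, 200 bands over 425–974 nm — the acquisition geometry; tests
and the acceptance script use 4×3 / 160×120 scenes, which preserve every
property being checked at a fraction of the cost).  Pixel spectra are exact
linear mixtures — max |cube − E·a| = 0 before noise — under one of three
abundance patterns: `pure_zones` (three pure stripes per kernel),
`radial_gradient` (glassy core → mealy rim with pure plateaus at core,
mid-annulus and rim so every endmember has recoverable pure pixels), and
`dirichlet` (α = 0.5 mixed pixels with a guaranteed pure fraction).
Additive Gaussian noise is calibrated to a stated SNR,
10·log₁₀(P_signal/P_noise) over foreground pixels; the platform stays
noiseless by default (black platform) or can carry a flat dark spectrum to
exercise background removal.  Ground truth (endmembers, abundances, labels,
per-pixel classes, per-kernel V, noise sigma) is recorded exactly.

Planted endmember spectra are base levels 0.75/0.45/0.18 plus
class-specific broad slopes (+0.30, +0.05, −0.08 across the axis — mealy
endosperm scatters strongly toward the NIR, glassy stays dark and flat) and
2–4 random Gaussian bumps.  Construction contracts, regenerated until all
hold: mean reflectance ordered mealy > intermediate > glassy, pairwise
spectral angle ≥ 0.1 rad, and ≥ 0.04 per-band RMS distance of each spectrum
from the others' span.  The last contract keeps the simplex well
conditioned: abundance noise amplification scales with the inverse smallest
singular value of E, and a near-coplanar triple makes 30 dB recovery
ill-posed for any unmixing method — real tissue classes are not
near-mixtures of one another.

**Crease phantoms** are rectangles/ellipses with rectangular or triangular
notches; truth is closed-form (rectangular: CD = depth, CW = width,
CA = depth·width; triangular: CA = depth·width/2).  A 1-px spine is carved
down the triangular notch center so the rasterized apex reaches the
analytic depth.  Rotation is applied after truth is fixed (truth is
rotation-invariant).

**Trait tables** draw i.i.d. standard-normal features; the response is a
sum of x + 0.3x³ over the informative features (x² when non-monotone) plus
Gaussian noise (default sd 0.1), with optional ±10-sd outliers whose ids
are recorded.

What the phantoms do **not** emulate: sensor spectral response functions,
stray light, specular highlights, spatial blur and chromatic registration
error, touching kernels, biological within-tissue spectral variability, and
non-linear (multiple-scattering) mixing.  Passing the phantom suite
establishes algorithmic correctness — exact recovery in the noiseless limit
and bounded degradation under calibrated noise — not field performance on
real cultivar panels.

## Reproducibility and problem sizes

Every stochastic step (skewers, N-FINDR/FIPPI initialization, CV folds,
forests, phantom generation) flows from explicit seeds; fixed seeds give
bit-identical endmember sets, fold tables and CLI outputs, which the tests
assert byte-for-byte.  Test and acceptance problem sizes — 4×3 scenes at
160×120 px with 200 bands (≈ 8k foreground pixels), 20 random 4-band NNLS
toys against the exhaustive 1e-3 lattice oracle, 600×300 rotation phantoms,
n = 100–300 trait tables — were chosen as the smallest sizes at which every
property under test is meaningfully exercised.
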