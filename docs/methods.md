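# Methods

This note documents the models and procedures implemented in `neuroquant`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that pin down
reproducibility.

## The recruitment statistic

mTOR recruitment to late endosomes (LEs) is measured per image as an
object-based enrichment ratio.  LAMP1-positive objects are segmented
(isodata threshold, 8-connected components, optional watershed splitting of
touching objects) and filtered by a strict size floor: only objects with
area **strictly greater than 25 pixels** survive (at the default 65 nm/px
this corresponds to an equivalent diameter of roughly 350 nm; "above"
is read as a strict inequality and the boundary case is exercised in the
tests).  The IN mask is the union of surviving object footprints; the OUT
mask is the set of pixels whose exact Euclidean distance *d* to the nearest
object pixel satisfies `gap < d <= gap + width` (defaults gap = 6 px,
width = 4 px), computed with a distance transform rather than iterated
dilation so the contract is unambiguous and oracle-testable.  Both masks
are intersected with a MAP2-derived dendrite mask (mean auto-threshold;
soma regions removed by a morphological opening of the MAP2 mask that
erases structures thinner than ~2x the opening radius, then a component
size floor).  The reported ratio is the ratio of *pooled-pixel* means —
one IN mean and one OUT mean per image — not a mean of per-object ratios;
a per-object mode exists in which shared ring pixels are assigned to the
nearest object (ties to the lower id).

The ratio is invariant under multiplicative intensity scaling but **not**
under additive offsets: on an image with uniform cytoplasm intensity *I*,
enrichment *E* and additive background *b*, the raw ratio is
`(E*I + b) / (I + b)`, not *E*.  Background subtraction therefore precedes
the measurement, and the test suite asserts both the invariance and the
non-invariance.

Measurements that are undefined (no objects, no ring pixels, zero
background) are kept in the output tables flagged invalid with a reason,
so per-condition *n* stays auditable.

## Rolling-ball background subtraction

The background estimate is the grayscale morphological opening of the image
with a ball-shaped structuring element whose height profile is the
spherical cap `b(q) = sqrt(R^2 - |q|^2)`; the subtraction returns
`image - opening`, which is everywhere in `[0, image]`.  The public
parameter is the ball **diameter** (the unit in which these analyses are
conventionally reported; R = diameter/2): 50 px for P-pS6 images and 75 px
for mTOR images by default.  Pixels outside the image are ignored (erosion
pads +inf, dilation pads -inf), and the implementation is checked for exact
equality against a per-pixel min-then-max brute force.  This is a clean,
testable dialect of the classical "roll a ball under the intensity
surface" method; it deliberately omits the legacy shrink/interpolate
approximation and pre-smoothing used by some implementations.

A consequence worth knowing: on shot-noise-limited data the erosion step
tracks local noise minima, so the background estimate under a structure is
biased low by roughly the size of negative noise excursions.  The residual
offset is common to IN and OUT pixels and pulls the measured ratio slightly
toward 1 at high enrichment (about -3 to -4% at E ≈ 2.2 under the default
photon budget).  PSF blur adds a small opposite bias (dendrite-edge ring
pixels dim faster than object interiors).  Both effects are characterised
by the enrichment-recovery tests; noise-free, blur-free recovery is exact
to <1%.

## Thresholding

Two auto-thresholds are provided.  **mean**: t is the arithmetic mean of
all pixels (used for the MAP2 dendrite mask in the recruitment pipeline);
adding a constant to the image leaves the mask unchanged.  **isodata**:
iterative intermeans on the raw values — t is a fixed point of
`t = (mean(values <= t) + mean(values > t)) / 2` — used wherever a method
is not otherwise specified (the classical ImageJ-style default).  Masks are
`values > t`, and every mask records its provenance (source channel, method
and the threshold actually computed); no anonymous mask reaches a
measurement.  A constant image yields an empty mask under `mean` and an
error under `isodata`.

## P-pS6 activity readouts

The whole-field activity transfers the MAP2 mask onto the
background-subtracted P-pS6 channel.  Somata are segmented from the P-pS6
image itself (isodata threshold, restricted to the MAP2 mask), then the
binary mask is **opened with a 5-px-radius disk before hole filling**:
proximal dendrites are bright enough to pass the threshold, and filling
first would flood regions enclosed by webs of crossing dendrites and merge
somata — opening first erases the thin stubs while leaving the (>=10 px
radius) somata intact.  Touching somata are split by a distance-transform
watershed and components under 200 px are discarded (the floor that
separates somata from bright dendritic segments at the default pixel
size).  Soma and dendrite compartments partition the MAP2 mask, so
`area_soma + area_dendrite = area_whole` and the whole-mask mean equals the
area-weighted compartment mean to machine precision — asserted on every
fixture.

The percentile-shift analysis computes the q-th percentile (default 75) of
the control per-soma intensity distribution using linear interpolation
between order statistics (numpy's default convention, pinned here so other
implementations can match) and reports the fraction of treated somata
**strictly above** that threshold.  Control versus itself yields ~`1 -
q/100` up to discreteness.

## Dendrite profiles and hot spots

A dendrite is a polyline from the soma outward.  Profiles sample the
channel at unit arclength steps by bilinear interpolation, averaged across
a 3-px band of perpendicular offsets.  Hot spots are local maxima whose
topographic prominence exceeds `0.5 x median(profile)`, thinned so no two
detections are closer than 10 px (the more prominent wins).  No published
quantitative criterion exists for these manually annotated spots; this
prominence rule is this package's operationalization, and results derived
from it should be reported together with its two parameters.  On synthetic
dendrites with planted bumps of twice the local baseline at photon-limited
noise, recall is >=90% with <=0.1 false detections per dendrite.

## Statistics

Two groups: Shapiro-Wilk normality at alpha = 0.05 on each group; both
normal → Welch's t-test (unequal variances assumed — safer than the pooled
test when nothing is known about variance homogeneity); otherwise a
two-sided Mann-Whitney U.  The U test is exact for small samples: for
tie-free data with both n <= 8 the null distribution comes from the
classical counting recursion; with ties at small n, every C(n+m, n) split
of the pooled sample is enumerated with midrank scoring; larger samples use
the normal approximation with tie and continuity corrections.  The exact
two-sided p is `P(|U - nm/2| >= |u_obs - nm/2|)` under the uniform null.

Three or more groups: if every group passes normality and Bartlett's test
does not reject homogeneous variances, one-way ANOVA with Tukey's HSD;
otherwise Kruskal-Wallis with Dunn's post-hoc test.  Dunn's z uses pooled
midranks with the tie-corrected variance
`(N(N+1)/12 - sum(t^3 - t)/(12(N-1))) (1/n_i + 1/n_j)` and Bonferroni
family adjustment (pinned for reproducibility; adjusted p never below
unadjusted, capped at 1).  For two groups the Dunn z satisfies z^2 = H
(tie-corrected Kruskal-Wallis), which the tests use as an independent
cross-check.  Significance stars are strict: * p < 0.05, ** p < 0.01,
*** p < 0.001; "partial inhibition" is flagged when a treatment differs
significantly from both the stimulated condition and its control.

The unit of analysis (field, neuron, soma) varies by readout; the caller
declares it by choosing which table feeds the comparison — the package
does not model within-image clustering (a known limitation: fields from
the same culture are treated as independent, as is conventional for these
readouts).

## The clustering index

The per-region contrast statistic is `(max - min) / mean` over the region's
pixels: 0 for a uniform region, growing as intensity concentrates.  The
variant `(max / min) / mean` is available behind a flag
(`literal=True`); it carries units of 1/intensity and is undefined when the
region minimum is 0, which is why it is not the default.

## The synthetic generator

`make_geometry` draws disk somata (radius 10-16 px) with 4 unbranched
piecewise-linear dendrites each (segments ~15 px, heading jitter <= 20°,
length 120-220 px, width 4-7 px), truncated at the image border.  LE disks
(radius 3.2-6 px, optionally annular to mimic the donut-like appearance of
larger LEs) are centred on dendrite centerlines at ~30 objects per 100 µm
of dendrite; placement rejects overlaps by default so each object's ring
background is unambiguous (an `allow_le_overlap` flag exists to stress-test
the ring-exclusion logic), and avoids somata so the objects are dendritic.
The default pixel size is 65 nm/px, chosen so the 25-px area floor
corresponds to ~350 nm equivalent diameter; it is a configurable default,
not a constant.

`render` composes, per channel: MAP2 = constant intensity on the mask;
LAMP1 = constant on LE footprints; mTOR = constant cytoplasmic intensity on
the MAP2 support multiplied by the per-object enrichment inside each LE;
P-pS6 = constant in somata, decaying as `exp(-s / L)` with arclength *s*
along each dendrite (default L = 80 px), plus optional Gaussian hot spots
(amplitude relative to the local baseline, sigma 3 px).  An optional
log-normal per-neuron activity factor (`pps6_soma_cv`, default 0) emulates
inter-neuronal response variability for per-soma analyses.  On top of the
signal: additive background (default 20) with an optional smooth shading
gradient, isotropic Gaussian PSF blur (optional; the optics are otherwise
unspecified), Poisson shot noise and Gaussian read noise.  The noise-free
render consumes no randomness, total noise-free mTOR intensity matches a
closed form (cytoplasm mass + enrichment excess + background), and
identical parameters and seeds reproduce outputs bit for bit.  Fixtures
are written as 16-bit TIFF (quantization happens only at write time, with
clipping warned) plus a schema-versioned JSON truth sidecar and a float32
label TIFF; reading them back round-trips exactly.

What the generator does **not** emulate: 3D structure, dendritic branching
and spines, time series, realistic arbor morphology, camera-specific noise
(fixed-pattern, EM gain), optical aberrations, chromatic shift between
channels, and biological covariation between markers.  Passing the
recovery tests therefore shows that the *measurement chain* is unbiased
and well-calibrated under controlled image formation — not that the
defaults reproduce any particular microscope.

## Problem sizes and numerical conventions

Tests and the acceptance script use 256x256 fields with 3 neurons (or
single-neuron fields for per-cell checks), 10-20 seeds per condition, 1000-
2000 null simulations; the full suite runs in about two minutes.
Coordinates are 0-based (row, col), pixel-centred; connected components use
8-connectivity; images are processed in floating point regardless of file
bit depth; CSV floats are formatted with `%.9g` and every output CSV
carries a header recording the tool version, configuration hash and seed,
making re-runs byte-identical.
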