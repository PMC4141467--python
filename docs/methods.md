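# Methods

This note records the model as implemented, the parameter choices and their
rationale, the numerical conventions, and what the simulations do and do not
establish.

## Model

### Photometry and encoding

Stimuli are strictly positive luminance fields (cd/m²) on a square pixel
grid with an angular calibration (deg/pixel; default 0.1 deg/px on a
256×256 canvas, i.e. a 25.6° field — large enough to put contextual borders
at or beyond the 10° integration range).  Generated stimuli carry an exact
ground-truth decomposition L = R × I with reflectance in (0, 1].

The first model stage measures each border between adjacent labelled
regions as a directed step in natural-log luminance, Δ = ln(L_b/L_a), where
L_a and L_b are mean luminances over the pixels of each region within 2 px
of the border.  Near-border sampling (rather than whole-region means) keeps
steps local, so shallow gradients elsewhere in a region do not contaminate
them.  Natural logs are used throughout; every exponent and slope the model
predicts is base-invariant.

The pre-logarithm sensory nonlinearity (cube-root for increments, linear
for decrements) is not simulated mechanistically; it is carried as the
post-log polarity gains w_inc = 1/3 and w_dec = 1 (see below), which is
algebraically equivalent for the quantities this package computes.

### Edge classification

Each border is classified **sharp** (candidate reflectance edge) or
**gradient** (candidate illumination gradient) by the median 10–90%
luminance transition width along the border normal, thresholded at 0.5°.
The threshold loosely corresponds to the coarsest spatial channels relevant
to lightness (~0.5 cycle/deg) and is configurable.  Sampling on each side
stops at the first pixel belonging to a different region, so the measured
transition is local to the border even for narrow regions.  Gradient-
classified edges receive a configurable residual gain `g_gradient`
(default 0: full exclusion).  Whether low-spatial-frequency borders are
fully excluded or merely down-weighted is an open empirical question; full
exclusion is the ideal-observer reading, and the gain exposes the
alternative.

### Selection

The region adjacency multigraph has one node per region and one arc per
*connected boundary component* (an interior Gelb paper therefore has two
distinct arcs to the background: above and below the row).  Path selection
operationalises border ownership:

* **wide** spotlight: the single shortest path from the designated common
  background to the target; ties are broken by maximal total shared-border
  length, and when parallel boundary components join two regions the
  longest one carries the step.  For a disk–annulus display this is
  background → annulus → disk; for plain Gelb papers it is the one-step
  path across the paper's own border with the background (inter-paper
  borders are never crossed); with an insulating frame it is
  background → frame → paper.
* **narrow** spotlight: one single-step pseudo-path per boundary component
  of the target, each treating the adjacent region as a local background;
  the target's lightness is the unweighted mean over pseudo-paths ("the
  average of the four border log ratios" for an interior paper).  The mean
  (not the sum) keeps narrow and wide outputs on the same scale.

Top-down gains multiply: spatial attention mask (sampled at the border
centroid) × interpretation gain (1 for reflectance edges, `g_illum`,
default 0, for edges attributed to illumination) × sharpness gain.  Gain
assignment is recomputed from scratch each time, hence idempotent.
Contour masking (flicker adaptation) is modelled as forcing one edge's gain
to 0; no neural fatigue dynamics are simulated.

### Integration

Scalar path lightness: Λ = Σ gain · w(sign Δ) · f(d) · Δ over the steps of
the selected path(s), with Δ the step crossed *toward* the target.

Distance kernels f(d), all with f(0) = 1, non-increasing, clipped to 0
beyond the 10° range cutoff:

| kernel       | form                          | default parameters |
|--------------|-------------------------------|--------------------|
| exponential  | exp(−d/τ)                     | τ = 10/ln 20 ≈ 3.338° |
| linear       | max(0, 1 − d/c)               | c = 10°            |
| log_linear   | max(0, 1 − b·log10(1 + d/d0)) | b = 1, d0 = 1°     |
| uniform      | 1                             | (ideal observer)   |

τ is calibrated so the exponential kernel reaches exactly 5% of its peak at
the 10° limit of contextual influence reported psychophysically.  The true
receptive-field profile is unknown; the kernel is a configuration flag, not
a claim, and the linear and log-linear forms are provided for comparison.

**Edge-to-target distance** for path sums is the minimum Euclidean distance
from the edge's boundary pixels to the target region, in deg.  An edge
abutting the target therefore has d = 0 and full weight — this is what
makes the Gelb exponents *exactly* w_inc / w_dec rather than kernel-scaled
versions of them, and it reproduces the annulus-width effect (the outer
border of a wider annulus is farther from the disk and contributes less).
A centroid-based metric was considered and rejected: it would attenuate a
target's own border by an arbitrary geometry-dependent factor and break the
closed-form exponents.

**Channel maps**: each edge broadcasts gain · w · f(d(x)) · |Δ| into the
pixels its light side faces (lightness channel L, weight w_inc) and its
dark side faces (darkness channel D, weight w_dec), where d(x) is the
distance from pixel x to the nearest boundary pixel of the edge.  "Faces"
is resolved by graph reachability: a pixel's region must be reachable from
that side of the edge without recrossing it, so induction from the outer
annulus border reaches the disk interior.  If removing the edge leaves its
two regions connected through other borders (a cycle), the facing sets
collapse conservatively to the two immediate regions.  Filling-in is thus a
byproduct of spatially-weighted edge signals; no diffusion dynamics are
involved.

With the exponential kernel the disk-interior achromatic color of a
decremental disk satisfies dAC/dρ = AC/τ along the radius, so a dark disk
(AC < 0) has a strict, curved maximum at its centre — the "inverted
meniscus".  With the linear kernel the interior profile is affine in the
edge distances (zero second derivative): a central peak may survive as a
slope change, but the meniscus curvature is specifically the exponential
signature, and that is what the tests assert.

### Readout and anchoring

AC(x) = L(x) − D(x).  Anchoring assigns reflectance R_white = 0.9 (the
conventional reflectance of white paper; the model itself fixes no white
point) to the anchor and scales other regions by exp(ΔΛ).  The default rule
is **highest reflectance** (anchor = region of maximal Λ); **highest
luminance** is selectable for comparison.  For maps, the anchor level is
the maximum over regions of the region-interior mean AC (interior = more
than 2 px from the region border) to avoid boundary-band artefacts; as a
consequence the pixelwise anchored map can exceed R_white within boundary
bands, while region-level values cannot.  Reported evidence that strong
induction can shift even the highest-lightness region challenges both
rules; no third rule is implemented.

## Experiments and problem sizes

All experiments are deterministic (no randomness anywhere in the pipeline)
and run on the default 256×256 canvas.

* **Staircase-Gelb** (`run_gelb_series`): 5 papers, 3° each, abutting,
  reflectances log-spaced 0.03–0.9, 1000 cd/m² spotlight on a 1 cd/m²
  surround — the dimmest paper is a 30× increment, as the compression
  account requires.  Insulation adds a 1°-thick frame of reflectance 0.9
  around the whole row (papers touch only the frame); the frame must be at
  least as reflective as every paper so the frame→paper step is decremental,
  and the generator raises otherwise.  The fitted exponent is exactly w_inc
  (plain) or w_dec (insulated) with residuals at float precision; this
  closed-form consequence is property-tested across random series.
* **Ideal-observer matching** (`run_ideal_observer_matching`): background
  10, match annulus 40, test disk 60 cd/m²; 8 test-annulus luminances
  log-spaced 20–200 cd/m² (one decade).  The match is found by two-point
  affine inversion of Λ in ln(match luminance) — exact, since Λ is affine
  for unit weights — with a bisection fallback for polarity-asymmetric
  configurations where the affine solve does not close.
* **Weight recovery** (`run_weight_recovery`): 8 disk luminances log-spaced
  annulus/5 to annulus×5 at fixed annulus (100) and background (10);
  regression of Λ on the positive and negative parts of the inner step.
  Λ stands in for the matched log luminance (they are affine in each
  other, so the coefficient ratio is identical) and the recovery is exact
  on the noiseless model data.
* **Scrambling** (`run_scrambling`): the default permutation swaps the two
  papers at positions 1 and 2.  A full reversal would preserve every
  paper's *set* of neighbours and is invariant even in narrow mode — a
  useful negative control, but not a default.
* **Annulus width / contour masking**: disk 30, annulus 90, background
  10 cd/m²; widths 1° vs 4°.

## Numerical conventions and degenerate cases

Region borders are pixel-aligned (a pixel belongs to exactly one region;
a boundary is a 4-neighbour label change), so edge extraction is exact.
Boundary components are grouped by midpoint adjacency (≤ 1 px), which
correctly merges the wrap-around background border of an end paper and
keeps above/below components of interior papers distinct.  Zero-contrast
edges contribute exactly 0 (sign-dependent weights never apply to Δ = 0).
Degenerate borders (< 2 px normal extent) raise on sharpness
classification.  Kernel evaluation rejects negative distances.  All
generators validate geometry (regions must fit the canvas, frames at least
one pixel thick, luminances positive).

## What the synthetic stimuli do and do not show

The generators produce exactly the idealised, noise-free, piecewise-uniform
displays of the modelled paradigms, with perfectly known R × I ground truth
— the regime in which the model's closed-form predictions (exponents 1/3
and 1, slopes 0 and −1, exact weight recovery) hold to machine precision.
Passing tests therefore validate the implementation of the theory, not the
theory against data: real scenes have sensor noise, non-uniform surfaces,
occlusion and illumination structure the region-label machinery does not
capture, and real observers produce noisy matches with partial (not zero)
gains on illumination edges.  `g_illum` and the kernel/weight parameters
are exposed so such intermediate cases can be explored.

## Known limitations

* Border ownership and attentional selection are realised as graph rules,
  not recurrent neural circuits; illusory-contour completion (Kanizsa) is
  out of scope.
* The sharpness classifier is a geometric stand-in for a spatial-frequency
  decomposition; no oriented filter bank is implemented.
* No temporal dynamics: flicker masking is modelled only as a gain of 0.
* Narrow-field quantitative fits to published scrambling datasets are not
  attempted; only the qualitative wide/narrow dissociation is asserted.
* Anchoring implements the two standard rules only, and chromatic stimuli
  (Watercolor) are not modelled.
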