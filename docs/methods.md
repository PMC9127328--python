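# Methods

## Image model and conventions

Images are single-channel 2D arrays of non-negative intensities (detector
counts taken as given; bit depth is not assumed).  Coordinates are 0-based
`(row, col)` pixels; rectangles are half-open.  All physical quantities are
derived through the pixel size: 25 nm for confocal/STED recordings, 64.5 nm
for epifluorescence.  Two-channel operations require identical pixel grids;
no drift or chromatic registration is attempted.

## Maxima detection

Detection reproduces an ImageJ "Find Maxima"-style procedure:

1. Gaussian blur (σ = 1 px default) of a working copy;
2. binary mask from an absolute threshold on the blurred image (1–5 a.u. is
   the realistic range; default 2, always recorded in reports);
3. within each 8-connected mask component, local maxima of the blurred
   image with a minimum separation of 2 px.  The ImageJ built-in's
   prominence semantics are not published, so this documented replacement is
   validated against synthetic ground truth (recall and precision ≥ 0.9 at
   3 maxima/µm² with a 60–90 nm PSF).  Plateau ties break to the smallest
   `(row, col)`, making detection deterministic and order-independent.

Per maximum the mean intensity is taken in a 5-pixel-diameter circular ROI
(the 13-pixel digital disc, matching an ImageJ oval of width 5) on the
**unsmoothed** image, and the subpixel position is the intensity center of
mass within that disc.  The raw rather than the smoothed image is used for
the centroid — the two options are equivalent for symmetric spots and raw
intensities avoid blur-induced coupling between nearby maxima.  The local
disc minimum is subtracted before the centroid so a constant background
cannot pull positions toward the disc center.  Maxima within 2 px of the
image border are flagged (`border`) and not localized.  The residual bias of
a truncated-disc centroid is below 0.08 px for noiseless spots and the RMS
error is ≤ 0.25 px at a Poisson peak of 50 counts.

Cluster size: a horizontal and a vertical 15 × 3 px line scan centered on
the pixel maximum, averaged across the 3-px width, each fitted to a
four-parameter Gaussian (offset, amplitude, center, σ; initialized from the
profile min/max/argmax).  The FWHM (2√(2 ln 2)·σ·pixel size) comes from the
better fit; a maximum is excluded when the best R² < 0.8 (`low_r2`) or the
fitted center leaves the middle third of the scan, positions 5–9 of 0–14
(`noncentered`).  Exclusion on either ground alone is applied: a fit that
fails either the quality or the centering check is not a trustworthy size
estimate.

Density is maxima count divided by ROI area, with area = pixel count ×
(pixel size/1000)² µm².

## Cross-channel association

Shortest distances use subpixel positions (they are computed precisely to
be used) and the Euclidean metric, implemented with a k-d tree and verified
exactly against an all-pairs oracle.  Secretase maxima are queries and APP
maxima targets by default (a CLI flag swaps them).  The null flips the
target image vertically and horizontally — a 180° rotation that preserves
the channel's count and intensity structure exactly — and re-detects; the
analysis ROI is rotated with the image.  The close cutoff is 50 nm; the
histogram bin width defaults to 25 nm (one STED pixel) with an explicit
overflow bin so counts are conserved, and display truncation never affects
the close fraction.  No edge correction is applied, which biases distances
upward when they are comparable to the ROI size; at a 50 nm cutoff inside
fields of tens of µm² the effect is negligible.  For spatially unrelated
channels the expected close fraction has the closed form
1 − exp(−λπr²) (nearest-neighbour CDF of a Poisson process), which the
flipped null reproduces within Monte-Carlo error.

## Coaggregation statistics

PCC is the plain Pearson correlation over membrane-ROI pixels — no
thresholding, no Costes/Manders variants.  rSDM is SD/mean of the ROI pixel
intensities (population SD, so a balanced binary ROI gives exactly 1.0); it
is scale-invariant and rises monotonically when a fixed amount of signal is
concentrated into fewer sites.  Corrected means subtract a background ROI
placed next to the sheet and may legitimately be negative.  Condition
summaries divide each replicate by the reference-condition mean (×100); when
an experiment column is present, sheets are first averaged per experiment
and the SD is taken across experiments, matching the usual replicate
hierarchy (3–10 experiments, 10–20 sheets each).

## FRAP

Recordings carry 3 prebleach and typically 117 postbleach frames at
1.77 Hz.  Per frame the bleach-ROI signal is background corrected, then the
postbleach values are divided by the corrected prebleach mean.  Drift QC
excludes recordings whose *reference*-ROI variation (range/mean over the
whole recording) exceeds 15% — range/mean is chosen over SD/mean because a
monotone focus drift is what the rule must catch; the boundary value 0.15
itself is retained (strict inequality).  Retained traces from one replicate
are averaged on a common time base, then fitted with
*y(t) = offset + R·t/(t + t½)* by bounded least squares (offset, R ∈ [0, 1.5];
t½ ∈ (0, 10 × recording length]) with three multistart t½ seeds.  Time is
measured from the bleach event, so the first postbleach frame sits at
t = 1/rate and y(0) = offset is the bleach floor.  Flat traces (R ≈ 0) and
fits pinned at a bound are flagged rather than reported as estimates.  The
fit is scale-equivariant in (offset, R) and recovers a noiseless hyperbola
to 4 decimals; at noise SD 0.02 the median t½ over 50 traces is within 10%
of truth.

## Densitometry

Input is a band-intensity table; band and background regions have equal
area, and corrected = integrated − background.  The cleavage ratio is
(sAPPα lysate + supernatant)/(mature + immature APP) and is invariant to
lane-wide exposure scaling.  Percent-of-wild-type divides each replicate's
ratio by the wild-type ratio of the same replicate (paired within blots)
before averaging.

## Synthetic data

The sheet simulator emulates what the analysis assumes about real
membrane sheets:

* Channel A: cluster centers from a homogeneous Poisson process
  (default 3/µm², within the observed 2.2–4.7/µm² range), 20–30 molecules
  per cluster scattered with Gaussian SD = diameter/4 (default diameter
  75 nm, matching 65–85 nm spots; ~95% of molecules fall inside the stated
  diameter).  The intensity profile within a cluster is not known
  empirically; the Gaussian scatter is a modeling choice.
* Channel B: points at their own density (default 3/µm²).  A planted
  fraction sits uniformly within 20 nm of *distinct* A cluster centers —
  distinct hosts because two sub-resolution points on one cluster are not
  two maxima, and the planted fraction is defined over resolvable maxima.
* Both channels are convolved with an isotropic Gaussian PSF (FWHM default
  75 nm, configurable over the 60–90 nm resolution range), a constant
  background (0.5 a.u.) is added and Poisson noise applied.  One A molecule
  contributes a 2 a.u. PSF peak; one B punctum 30 a.u. (±30% uniform),
  reflecting that secretase maxima are brighter than single-fluorophore
  signals.  Emitters keep a margin of 2 PSF FWHM from the field edge
  (interior membrane regions are analyzed); densities refer to that
  interior region, exposed as an ROI.
* Cross-linking reassigns all A molecules to a small number of aggregate
  sites drawn from the original centers and optionally drags a fraction of
  B points to the nearest site (scatter: uniform within diameter/4).  Zero
  co-drag models a non-coaggregating secretase, positive values a
  coaggregating one.

Not modeled: camera gain/EMCCD noise, STED depletion physics, acquisition
photobleaching, membrane holes or uneven labeling efficiency.  Passing
tests therefore demonstrate correctness of the *measurement* chain under
the stated point-process model, not robustness to every artifact of real
micrographs.

FRAP traces are sampled directly from the hyperbolic model plus Gaussian
noise; blot lanes add multiplicative noise (relative SD) to true band
intensities plus a local background measurement with the same noise.

## Problem sizes and determinism

Simulated fields default to 256 × 256 px at 25 nm (6.4 × 6.4 µm, interior
≈ 37 µm², roughly 110 clusters and 110 B maxima per field) — large enough
that per-field close-fraction statistics are stable at the percent level,
small enough that the full Monte-Carlo suite (hundreds of fields) completes
in about a minute.  Every generator is deterministic given its seed; recipe
reports re-serialize byte-identically on rerun and record every threshold
used.

## Known limitations

* At densities approaching one maximum per PSF area, nearby emitters merge;
  the simulator warns, and detected densities then underestimate truth.
* The flipped null preserves within-channel clustering but, like the
  original procedure, assumes the membrane region is homogeneous; strong
  intensity gradients would bias it.
* No multi-emitter fitting, elliptical PSFs, 3D stacks or proprietary
  microscope formats.
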