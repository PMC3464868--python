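# Methods

## Strain definition and conventions

All strain measures in this package are Lagrangian length ratios,

ε(t) = 100% · (L_t − L₀) / L₀,

where L is the endocardial border length (sum of Euclidean distances
between consecutive contour points, plus the implied closing segment for
closed borders) and L₀ is the **maximal** border length over the cycle.
Referencing the maximum rather than frame 0 makes ε read as systolic
shortening regardless of which phase the acquisition was triggered on; the
curve is exactly zero at the reference phase, negative during contraction,
and the reported peak is the absolute value at the extreme phase.
Coordinates are physical millimetres throughout (0-based, origin at the
top-left pixel centre, x along columns, y along rows); closed contours
never repeat their first point.

## Endocardial border delineation (EBD)

Sparse operator-placed border points are densified by monotone
(shape-preserving) piecewise cubic Hermite interpolation of x and y against
the cumulative chord-length parameter; closed borders use a periodic
parameterisation that includes the closing span. Monotone tangents avoid
the overshoot loops that natural cubic splines produce on sparse manual
points. Output points are uniform in the parameter; when the requested
count equals the anchor count the anchors are returned as-is (the
interpolant passes through its nodes). The default of 200 output points
keeps the polyline length error of anatomical curvature at 1 mm resolution
below 0.1% — 12 anchors on a circle densified to 360 points recover the
circumference to better than 0.5%, and doubling the density changes a
phantom strain estimate by less than 0.05 strain-points.

## Feature tracking

The tracker follows an operator-drawn border through the cycle in four
stages per frame:

1. **Template matching.** For each contour point an 11×11 px intensity
   template is matched by normalised cross-correlation (the
   maximum-likelihood matcher under Gaussian noise with unknown gain)
   within a ±5 px search window, with sub-pixel localisation by parabolic
   fit of the correlation peak. Templates are cut from the *reference*
   frame (frame 0) at each point's material position, and the search window
   is centred on the point's position tracked on the previous frame.
   Matching against the reference rather than the previous frame means
   per-frame matching errors do not accumulate into drift and the matcher
   cannot lock onto frame-to-frame correlated noise when the tissue is
   still; the previous-frame position still provides the motion prediction
   that keeps the residual search small. Zero-variance (flat) templates are
   replaced by the local average of valid neighbours, and a correlation
   peak on the rim of the search window is not treated as a localised
   match. Open-border end points (the annulus corners, the only tangential
   landmarks on straight walls) use a slightly larger template so the
   corner structure outweighs the featureless blood-pool channel, and
   their per-frame step is capped at 3 px — a physical bound on landmark
   motion at 30–40 ms per frame.
2. **Border-normal refinement.** Each matched point is nudged along the
   local contour normal onto the steepest bright-to-dark intensity
   transition (cavity into wall) within ±2 px. The transition polarity is
   estimated once from the initial contour. The directional-derivative
   profile is weighted by a Gaussian prior (σ = 1 px) centred on the
   matched position so that marginally steeper slopes further out — texture
   features, neighbouring structures — cannot out-vote the adjacent border;
   points whose best profile peak is weak (below 30% of the contour median)
   keep their matched position.
3. **Spatial smoothing.** Displacements are passed through a median filter
   (outlier rejection) and a moving average over 5 adjacent contour points,
   periodic for closed borders. Open-border end points are exempt: on
   straight walls the interior points carry no tangential signal (aperture
   problem), and averaging the well-anchored annulus corners with them
   would make the endpoints lag.
4. **Regularisation and closure.** Each point is pulled 30% of the way
   toward the position on the current polyline at its original arc-length
   fraction, turning the tangential random walk of aperture-limited points
   into a mean-reverting process without changing border shape or length
   (exact for homogeneous deformation); the residual deviation from the
   arc-length target is capped at 2 px so no point can slide away along
   the border. After the last frame one extra
   matching step back onto frame 0 measures the cycle-closure residual,
   which is removed by linear redistribution (the cycle is periodic).
   Finally a [0.25, 0.5, 0.25] temporal filter is applied to each point
   trajectory (cyclic when drift compensation is on); at 25 phases per
   cycle it attenuates a smooth systolic excursion by only ~2% while
   suppressing single-frame jitter.

Defaults (template half-width 5 px, search radius 5 px, smoothing window
5 points, drift compensation, normal refinement and temporal smoothing on)
assume ~1 mm/px imaging at 30–40 ms per frame, where inter-frame tissue
motion is at most a few pixels.

Global longitudinal (open border) and circumferential (closed border)
strain are the border-length strain of the tracked contour. Radial strain
is the mean over points of 100·(r_t − r_ref)/r_ref, with r the distance to
the cavity centroid of the maximal-area frame — an endocardial surrogate
for wall thickening. Segmental strain partitions the reference contour
into equal-arc-length runs with shared boundary points, so segment lengths
sum exactly to the border length; all segments are referenced to the
global reference frame, which makes the length-weighted mean of segment
strains equal the global strain identically. The default of 6 segments is
a convention choice; nothing in the method fixes the partition.

## Synthetic phantom

The phantom emulates balanced-SSFP cine slices: bright blood pool (1.0),
darker myocardium (0.5), background (0.1), logistic edge profiles of width
0.7 mm standing in for partial-volume blur at the default 1 mm/px, 25
phases per cycle at 40 ms. Two geometries are rendered: a short-axis ring
(circular cavity, 25 mm end-diastolic endocardial radius, 8 mm wall) and a
four-chamber "U" (two straight walls joined by a 15 mm apical cap, 160 mm
end-diastolic border length, with the blood pool continuing past the
annulus plane as an atrium and the wall terminating there, which gives the
annulus corners their corner contrast).

The deformation is an isotropic scale s(t) = 1 − a·w(t) about a fixed
centre, where a is the prescribed peak shortening and w a raised-cosine
systolic waveform peaking at round(phases/3) followed by diastasis — the
simplest smooth, cyclic, roughly physiological activation. Because a
similarity transform scales every length by s, the ground-truth contour
track and strain curve are exact closed forms, and frames are rendered by
sampling the end-diastolic intensity field at back-transformed material
coordinates, so everything in the image moves exactly with the tissue.

Texture: dark Gaussian dips (σ = 2 mm, amplitude 0.25) at seeded uniform
material positions in the wall mimic the trabeculation and brightness
inhomogeneity that feature tracking exploits. Dips are kept in the deeper
half of the wall (50–90% of wall thickness from the endocardium) so they
texture the templates without corrupting the border's own gradient, and
the basal 8 mm next to the annulus stays feature-free — trabeculation
belongs to the ventricle, and the annulus corner is the only tangential
landmark of the open border. Gaussian pixel noise (per-pixel, per-frame,
from the phantom seed) is added last, so changing the noise level never
moves the ground truth.

What the phantom does **not** emulate: deformation heterogeneity (strain
is spatially uniform by design, which makes global = segmental truth and
isolates tracker error), torsion, through-plane motion in the rendered
images, papillary muscles crossing the border, receive-coil shading, and
ultrasound speckle physics. Passing the phantom suite therefore shows that
the pipeline recovers a known uniform deformation at realistic contrast
and noise — not that it handles every pathology of clinical data.

## Out-of-plane bias model

Circumferential strain measured on a fixed short-axis plane is biased low
when the heart moves longitudinally: the cavity is modelled as a truncated
cone (base radius R_b > apex radius R_a over long axis Λ, default
40/20/80 mm). The plane sits at fraction f of the long axis; in diastole it
reads circumference L₀ = 2π·R(f). At end-systole the tissue has moved a
distance d toward the apex, so the plane now intersects material that
started at the more basal level f·Λ − d with a larger radius; after the
true material shortening its circumference is still larger than the true
in-plane systolic circumference, so
CS = 100·(diastolic − systolic)/diastolic is reduced — equal to the true
value only at d = 0 and strictly decreasing in d. The cone needs an
explicit long-axis length to convert millimetres of displacement into a
radius change; 80 mm is a typical ventricular long axis.

## Agreement statistics

Bland–Altman: bias = mean(a − b), limits = bias ± 2·SD(a − b) with the
sample (n−1) standard deviation — the factor is exactly 2, not 1.96, and
small-n observer studies warrant the sample SD. The coefficient of
variability is COV = 100 · SD(a − b) / mean of all 2n values: zero exactly
when the methods agree on every pair, invariant under a common positive
rescaling, undefined (an error) when the grand mean is zero. The
Bland–Altman report carries the COV alongside (NaN in the degenerate
zero-mean case).

## Validation workflow and problem sizes

`run_validate` builds a seeded suite of 20 phantoms cycling through
strains {10, 15, 20, 25}%, noise levels {0, 0.05, 0.1} and both
geometries — the strain range brackets the global strains seen in adult
ventricles. Feature tracking starts from the frame-0 truth contour and
works on the rendered images only; EBD receives every 10th truth point per
frame as "manual clicks" and densifies them. The summary reports per-method
truth-recovery errors and the EBD-vs-FT Bland–Altman/COV agreement, and
every run writes its fully resolved configuration for reproducibility. The
suite completes in under a minute on one CPU; `scripts/acceptance.py` runs
exactly this suite plus the cone model.

## Known limitations

* The tracker is tuned for sub-pixel cyclic motion of a few px/frame; it
  has no multi-resolution stage and will lose features that move farther
  than the search radius between frames.
* Arc-length regularisation and the equal-arc segmental partition both
  assume approximately homogeneous tangential deformation; strongly
  heterogeneous segmental strain would be smoothed toward its mean.
* Radial strain tracks only the endocardium; it is a surrogate for wall
  thickening, not a transmural measure.
* DICOM support covers single-slice cine series ordered by trigger time or
  instance number; multi-slice stacks and DICOM writing are out of scope.
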