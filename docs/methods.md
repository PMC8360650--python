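# Methods

This note documents the models, conventions and numerical choices behind
kerafil's measurement operators, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Conventions

All physical lengths are carried in Ångström internally; nanometres
appear in simulator specs and reports where that is how the quantity is
conventionally quoted (diameters, persistence lengths). Image coordinates
are 0-based pixel indices, origin top-left, `x` = column, `y` = row. The
in-plane angle ψ is measured counter-clockwise from the image vertical to
the filament axis, so a segment extracted with its recorded ψ has a
vertical filament axis; a horizontal filament has ψ = 90°. Particle
tables use a single-block STAR dialect with RELION-style tags where they
exist plus `_kfSegmentIndex`; unknown tags survive read → write.

## Synthetic forward model

The generator emulates what 2D class averages and micrographs of
intermediate filaments look like *geometrically*:

- **Cross-section**: a hollow cylinder (outer diameter `diameter_nm`,
  inner radius `(1 − wall_fraction)·outer`, default wall fraction 0.4)
  with an optional central core rod. The projection of this density is
  analytic chord length, which reproduces the characteristic profile of
  real classes: edge maxima at the wall, a weaker central bump from the
  core.
- **Helical pattern**: a single-start sinusoidal surface wave — the
  density is `base(x)·(1 + m·cos(2π·s/P + azimuth(x)))` with modulation
  depth `m = 0.5` by default. The true 3D motif of the filament surface
  is unknown; this is the simplest model that produces a one-pitch
  autocorrelation peak. A "straight-pattern" filament is the same model
  with `m = 0`.
- **Tilt**: applied as axial compression of the rendered pattern by
  cos θ (render on a taller canvas, rescale, center-crop), matching the
  in-silico tilting procedure the analysis itself models. It is *not* a
  3D ray casting; foreshortening of the pattern is the only tilt effect
  represented.
- **Bending**: pixels are assigned (signed lateral offset, arc position)
  of their nearest point on a finely resampled contour; valid while the
  bending radius is large against the filament radius.
- **Noise**: additive white Gaussian after projection, with the
  noise-free render normalized to peak 1, so `noise_sigma = 1/SNR`.
  There is no CTF, no detector model, and no structured background; an
  optional low-pass is deliberately omitted because the analyses under
  test are geometric.
- **Worm-like chain** (2D): tangent increments Gaussian with variance
  `step/Lp`, giving ⟨cos Δθ(s)⟩ = exp(−s/2Lp). The in-plane convention is
  documented explicitly because the 3D convention (exp(−s/Lp)) differs
  by the factor of two.

Default parameters are the measured filament geometry: 10.1 nm outer
diameter, 163 Å pitch, ring of 6 protofilament blobs at 3.5 nm radius
(σ = 0.75 nm) around a core of 80 % blob amplitude. Study geometry
constants — 2.206 Å/px acquisition, 250 px (≈55 nm) boxes, 50 Å
inter-box distance, 132 Å back-plotting mask, 4.2 nm slabs — are the
`PipelineConfig` defaults.

Because the generator is geometric, passing closure tests demonstrates
that the *measurement operators* are correct and unbiased under the
stated noise model; they do not demonstrate robustness to CTF fringes,
ice-gradient backgrounds, crossing filaments inside one box, or
classification error, none of which the simulator produces.

## Pitch estimation

The axial signal is the mean intensity per row over columns within the
lateral mask (default 132 Å), mean-subtracted. The autocorrelation uses
the biased estimator (division by n), which guarantees |acf| ≤ 1 and
stable peak prominences. The biased estimator multiplies the true
autocorrelation by the triangular taper (n − k)/n, which drags peak
*positions* toward smaller lags (≈2.6 Å at 163 Å in a 250-row box), so
peak detection and prominence are evaluated on the biased curve while the
location is refined on the taper-corrected curve, followed by a parabolic
sub-sample fit. The first peak with lag ≥ 60 Å (skipping the zero-lag
shoulder) and prominence ≥ threshold is reported — "first" resolves the
fundamental/harmonic ambiguity toward the fundamental.

The prominence threshold (default 0.5) was calibrated on simulations at
the working box size: helical classes at SNR 3 yield band-peak
prominences ≥ 1.05, while white noise and unmodulated filaments stay
below 0.35. The same threshold drives the helical/straight pattern
labels, replacing by-eye cluster assignment with a reproducible
criterion.

## Diameter measurement

The lateral profile subtracts a baseline equal to the mean over the outer
10 % of columns per side, which pins the off-filament level to ≈0 by
construction. The diameter is the distance between the outermost
zero-crossings bracketing the central positive region. Because the
baseline convention leaves the tail fluctuating *around* zero, the run is
walked outward on the raw profile until it sinks to a noise floor (2×SD
of the outer samples); a Gaussian-smoothed copy (σ = 1 px) only anchors
the central region. Crossing positions are then interpolated to zero on
the raw profile (extrapolated through the noise floor along the edge
slope when the bracketing sample is positive; gap midpoint when the tail
is exactly zero). Smoothing is deliberately excluded from the crossing
location itself: on zero-background profiles a smoothing kernel extends
the positive support by its own width and inflates diameters by up to
~2 nm. Diameters are reported to 0.1 nm.

The mean profile over classes is unweighted (each class contributes
equally); the particle-weighted variant is available through
`diameter_distribution`, which also reports the weighted mean ± weighted
SD.

## Tilt model

`tilt_project` treats the class as a planar density tilted about the
in-plane axis perpendicular to the filament axis and orthographically
projected: an axial rescale by exactly cos θ (bilinear, center-
preserving), lateral size unchanged. Under this model the 163 → 132 Å
compression corresponds to θ = acos(132/163) = 35.9°, slightly above the
~34° quoted alongside those pitches elsewhere; the exact tilting
implementation behind that pairing is not specified, so this package
documents the cos model and treats ±4 Å / ±2° as the agreement band for
that worked example.

## Back-mapping

Classes are masked laterally to the central 132 Å with raised-cosine
edges (10 px ramps; "soft edges" have no prescribed taper, so the ramp
shape and width are package constants), cropped axially to a soft window
of half-length 2×inter-box minus a 2 px interpolation margin, rotated by
+ψ and accumulated at the picking coordinates as a weighted mean with the
soft-mask weights. The "at most four overlapping classes" rule is
enforced exactly per filament by a streaming per-pixel top-4 selection on
soft-mask weight — order-independent and exact (keeping the four largest
weights seen is invariant to arrival order). Crossing filaments
superimpose; the bound applies within a filament, since no overlap rule
can prevent two distinct filaments from sharing pixels.
"Normalized to equal intensity" is implemented as unit mean intensity
over each filament's footprint.

Straightening resamples the image along spline-contour normals at 1-px
arc steps (bilinear, like every other resampling in the package), so the
straightened image's axial extent equals the contour arc length within a
pixel.

## Persistence (L90)

Tangent angles come from central differences on the resampled contour,
unwrapped cumulatively so S-curves that net 0° still expose ±90° swings
through windows; endpoint angles are linearly extrapolated because
one-sided differences lose half a step of turn at each end (an exact
quarter circle would otherwise never reach 90°). The minimal 90° window
is searched over *all* start positions (a from-origin mode is available
as a flag), with sub-step interpolation of the crossing and a 1e-9 rad
tolerance on the 90° threshold against floating-point rounding.
Population statistics use the sample (n−1) SD, appropriate for the small
n of traced-filament studies.

The L90 of a selected bent subpopulation systematically underestimates
equilibrium stiffness: in worm-like-chain ensembles with Lp = 300 nm,
chains that happen to turn 90° within a 600 nm trace average L90 far
below πLp/2, and tightening the selection window lowers the mean further.
This is asserted as a property test and mirrors why such a measurement
must not be read as an equilibrium persistence length. Equilibrium-style
tangent-correlation fitting is provided only as a simulator validation
utility.

## Cross-sections

Slices are Gaussian-blurred at half the expected blob width before
analysis — the standard denoising step for cross-section inspection; it
preserves blob positions. The ring radius is auto-detected as the
outermost prominent peak of the *circumference-summed* radial intensity:
summing rather than averaging suppresses the central core (few pixels)
relative to the ring (a full circumference), which otherwise dominates
the radial mean. Protofilaments are counted as peaks of the angular
profile over the ring band (ring ± blob σ), circularly smoothed at half
the expected angular blob width and detected with wrap-around so a peak
at the ±180° seam counts once. Counts whose angular gaps are strongly
non-uniform (max gap ≥ 1.5× median) are flagged low-confidence — the
signature of neighboring protofilament densities merging into one.

Core presence requires the blurred interior (ring radius minus 2σ
clearance) to exceed both background mean + 5 SD and 25 % of the wall
peak amplitude; wall tails alone reach ~10 % of the wall amplitude at the
interior boundary, and with ~200 interior pixels a 2 SD rule would fire
on pure noise. The core *position* is a least-squares fit of an isotropic
Gaussian core plus an azimuthally symmetric wall-tail term over the ring
interior: jointly modelling the wall is what keeps near-wall cores from
being dragged outward, a ≥0.3 nm bias for any plain centroid or
mean-shift estimate. Mean localization error in closure tests is
< 0.1 nm across offsets 0–2 nm at SNR 5.

Sub-tomogram 2D classification of cross-sections is replaced by direct
per-slice measurement; a classification engine is out of scope.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
the study's acquisition geometry: 250 px boxes at 2.206 Å/px for
pitch/tilt/classification (1.075 Å/px for sub-pixel diameter checks),
64 px cross-sections, 480 px micrographs, 20 seeds per stochastic
closure sweep, 400–2000 worm-like chains for ensemble statistics. These
sizes were chosen so every estimate's sampling error sits well inside the
asserted tolerance while a full run stays in the minutes range on one
core.

## Known limitations

- No CTF or structured-noise simulation; closure results bound
  algorithmic bias, not robustness to real-micrograph artifacts.
- The bent-filament render is a nearest-point sweep, inaccurate when the
  bending radius approaches the filament radius (self-overlap).
- `tilt_project` is a planar foreshortening model; thick-specimen
  projection effects (depth blur, wall asymmetry under tilt) are not
  represented.
- Protofilament counting assumes blobs on a single ring; double-wall or
  unraveled architectures would need a different model.
- The STAR dialect is deliberately small (one data block, one loop);
  multi-block RELION optimiser/model files are out of scope.
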