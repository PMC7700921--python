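# Methods

`impteval` evaluates intensity-modulated proton therapy (IMPT) plans for
distal esophageal cancer the way a proton center's physics group does before
approving a plan: dose-volume-histogram (DVH) indices on the nominal
geometry, robustness bandwidths under setup and range uncertainty,
a machine-timing-based simulation of the interplay between spot-scanning
delivery and breathing motion, and normal-tissue complication probability
(NTCP).  Because no patient data ship with the package, a synthetic
phantom/plan cohort generator supplies the inputs; the paired statistical
machinery is additionally validated against a published two-group NTCP
table that is packaged as a CSV fixture.

## Synthetic anatomy and cohort

A phantom is an elliptical-cylinder body on a regular grid (default
96×96×120 voxels at 2.5 mm; axes x = R-L, y = A-P, z = S-I) containing an
S-I-elongated two-level target near the posterior midline (CTV_high inside
CTV_low), the optimization target volumes (OTV = CTV + 5 mm Euclidean
margin, implemented as a distance-transform threshold so the margin is
rotation-invariant), and geometric organs at risk in fixed anatomically
plausible positions: liver right-lateral, heart anterior-superior, spinal
cord posterior midline (4 mm radius), lungs superior-lateral, stomach left,
kidneys posterior-inferior.  Requested target volumes are realized within
5% by bisecting a scale factor on the ellipsoid semi-axes.

Matched cohorts sample CTV_high in 132–339 cm³ and CTV_low in 243–733 cm³
log-uniformly (log-uniform reflects the right-skew of clinical target
volumes), breathing amplitude uniformly in 0.5–1.0 cm; the two members of a
pair share the amplitude exactly and the volumes within ±10%, and are
planned with the two beam configurations under comparison:

* **S-I group** — two posterior oblique beams rotated into the sagittal
  plane (gantry 155°/205°, couch 270°), entering inferior- and
  superior-posteriorly;
* **R-L group** — the same gantry obliques in the transverse plane
  (couch 0°), entering right- and left-posteriorly, with optional anterior
  supplements.

Every generated object is a pure function of its configuration and a seed.

## Dose model

Each spot deposits `MU · A · L(z; R·s) · G2(lateral; σ)`: a 2D lateral
Gaussian (σ = 5 mm) times a depth-dose `L` that is a constant entrance
plateau (0.35 of peak) plus a Gaussian Bragg peak (σ_z = 3 mm) at the
Bragg-Kleeman range `R(E) = 0.0022·E^1.77` cm; the machine provides 97
energy layers from 71.3 to 228.8 MeV (uniformly spaced, as the true layer
list is machine-specific).  The medium is water-equivalent, so depth is
geometric distance from the body-entry point of the ray; consequently a
rigid whole-patient translation acts purely as a lateral displacement of
the spot pattern relative to the anatomy (the shift component along a beam
axis is inert — a documented simplification of the homogeneous medium).

The engine rasterizes each layer's spot MU onto a 2.5-mm lateral grid with
bilinear deposition, applies one Gaussian filter, and samples the filtered
fluence at voxel positions.  This is integral-preserving but broadens the
effective lateral σ by ≈1% (up to a few % error on a single-spot peak);
plan-level doses are unaffected after normalization.  An exact single-spot
evaluation path exists and cross-checks the rasterized path in the tests.

The absolute calibration `A = 200 Gy·mm²/MU` fixes the otherwise arbitrary
MU scale so that a 50/45 Gy[RBE] in 25 fractions prescription yields
per-fraction spot weights with median ≈ 0.08 MU — above the 0.04 MU
iso-layer repaint limit, so the repainting mechanism is operative for
typical spots exactly as on the modeled synchrotron.

## Planning

Spots are laid per energy layer on a 6.5-mm lateral grid over the layer's
OTV cross-section plus a one-spacing margin ring (guaranteeing spots
outside the OTV edge); layers are chosen so Bragg depths tile the OTV depth
extent at 6-mm spacing.  Weights are fitted per field (SFO-style: each
posterior field carries an equal share of the prescription) by non-negative
least squares over ≈2200 sampled OTV voxels, with the boost OTV weighted
5× (coverage priority) and a small spinal-cord sparing term (weight 0.1).
The solver is FISTA projected gradient (600 iterations), chosen because
dense active-set NNLS is impractical at thousands of spots.  The plan is
normalized so CTV_low D95% equals 45 Gy on the nominal averaged-breathing
geometry, then post-processed to deliverable MU (sub-minimum spots rounded
up or dropped, then renormalized).

A known limitation: with the stacked entrance plateaus of this kernel, the
two sagittal posterior fields of the S-I group both traverse the midline
cord, and no spot-weight redistribution can bring the synthetic cord Dmax
(~50 Gy) below the 45 Gy limit; the R-L geometry passes (~41 Gy).  The
*direction* of this group difference — S-I trades cord dose for better
lateral-organ sparing — is the clinically expected behavior, but the
magnitude is exaggerated relative to a heterogeneity-corrected dose
algorithm, and the constraint report flags it rather than failing the
cohort.

## Plan quality and robustness

Dx% inverts the empirical survival function with linear interpolation
through the points (k-th hottest dose, k/n), clamped to the hottest voxel —
so four 1-cc voxels of {10,20,30,40} Gy give D2cc = 30 Gy, matching the
"minimum dose covering the hottest 2 cm³" reading.  VxGy is an exact voxel
count; Dmean/Dmax come from raw voxel values, never from bins.  Constraint
compliance uses strict inequality, and a missing structure is reported as
not-evaluable rather than silently passed.

The uncertainty set holds 13 scenarios: nominal, ±3 mm setup shifts along
each axis, ±3% range scaling, and four combined members pairing the ±S-I
shift with each range scaling (S-I being the dominant uncertainty axis;
the combination axis is configurable because the composition of the
perturbed set beyond shifts and range scalings is a convention).  The
normalization factor is fixed by the nominal scenario and reused for all
perturbed doses.  Robustness of an index is its bandwidth: max − min over
the 13 scenario values (horizontal for D-type, vertical for V-type
indices); smaller is more robust.

## Delivery timing and repainting

The timing model is a Hitachi-style synchrotron: 8.7 MU/s spot dose rate,
1.93 ms magnet preparation + 3 ms interval between spots (4.93 ms dead time
per spot), 1.91 s energy switch, 7.9 s of beam-on budget per extraction
spill, 0.1 s extraction setup and ~1 s acceleration per new spill, with
multi-energy extraction (layers share spills; only beam-on time consumes
the spill budget).  Layers are delivered from highest to lowest energy in
serpentine scan order.

Iso-layer repainting splits each spot above the applicable maximum MU
(0.04 MU when the motion amplitude is ≤ 5 mm, 0.01 MU above) into full
repaints plus one residual; residuals under the 0.003 MU minimum are
rounded up when above half the minimum and dropped otherwise (a residual of
exactly half is dropped).  Pass j of a layer delivers the j-th piece of
every spot, so the repaints of a spot are spread across the layer's
delivery time — the averaging mechanism of repainting.  Each field keeps an
MU ledger (planned, delivered, rounded-up, dropped) whose conservation
bound is asserted in the tests.

## 4D dynamic dose (interplay)

Breathing is a square-occupancy two-phase trace (exhale = reference for the
first half-cycle, inhale for the second; period 4 s by default) — the
two-equally-weighted-extreme-phases simplification; the starting phase is
drawn uniformly per field per fraction from a counter-based generator keyed
by (seed, case, fraction, field), so draws are reproducible and independent
of evaluation order.  Each delivered piece is assigned to the phase active
at its delivery midpoint.  Phase doses are computed on the phase geometry
(patient rigidly displaced by the motion vector; dose expressed on the
room-fixed grid) and the inhale dose is mapped onto the reference grid by
the inverse displacement — trilinear, exactly invertible for the rigid
synthetic motion, with any clipped dose mass logged.  A general per-voxel
displacement hook exists but only the rigid implementation ships.

Because dose is linear in MU and the two phase geometries repeat every
fraction, the accumulation sums each spot's delivered MU by assigned phase
across all 25 fractions first and then computes one dose per phase; this is
numerically identical to fraction-by-fraction accumulation and is what
keeps a full-course interplay evaluation at seconds per patient.

Two oracles anchor the chain: with zero motion the dynamic dose reproduces
the static exhale dose to within 0.5% of the maximum dose voxelwise
(residual differences are exactly the repaint rounding); with the repaint
maximum forced to 0.002 MU every spot spreads over many breathing cycles
and the dynamic dose converges to the equal-weight two-phase average (CTV
mean dose within 1%).

## NTCP

gEUD = (Σ vᵢDᵢᵃ)^(1/a) with equal voxel weights (computed max-scaled so
large exponents cannot overflow), and NTCP = 1/(1 + (TD50/gEUD)^(4γ₅₀)).
Default endpoint parameters (literature-derived stand-ins, configurable):
pericarditis TD50 = 48 Gy, γ₅₀ = 3, a = 3; liver failure TD50 = 40 Gy,
γ₅₀ = 2.8, a = 3; pneumonitis TD50 = 24.5 Gy, γ₅₀ = 2, a = 1.  No
fractionation correction is applied.  NTCP is evaluated on the nominal
averaged geometry.

## Statistics

The paired comparison is the Wilcoxon signed-rank test with zero
differences discarded, average ranks for ties, tie-corrected variance, and
a two-sided normal approximation without continuity correction — the unique
convention that reproduces the packaged published table's p-values
(0.0208, 0.5748, and 0.3173 for the degenerate single-nonzero-pair case)
to four decimals, which the test suite asserts.  Summaries are median
(range); box-plot statistics use linear-interpolated quartiles with the
1.5×IQR outlier rule.  The published summary ranges turn out to be whisker
ranges under exactly that rule (not raw extremes), which `boxplot_stats`
reproduces for all six endpoint/group combinations — a second, independent
check of the quartile convention.  An exact-permutation p-value is
available behind `method="exact"` for tie- and zero-free samples.

## Problem sizes and determinism

Default problem sizes: ~1.1 M voxels per phantom, ~3400 spots per
two-field plan, 25 fractions, 13 scenarios × 3 phases per robustness
evaluation.  The test suite exercises the full chain on a 48×48×60 (5 mm)
phantom and runs the interplay oracles at full voxel pitch on a 96³
region; `scripts/acceptance.py` uses a 64×64×80 (3 mm) phantom for its
end-to-end pass.  Everything is deterministic given the configuration and
seed; pipeline outputs carry a manifest with file checksums and a config
hash.

## What the synthetic cohort does and does not show

The generator emulates the study conditions (volume and motion ranges,
matched pairs, prescriptions, beam geometries, machine constants) but not
real anatomy: no CT densities or heterogeneity, geometric organ shapes,
rigid single-vector breathing, an analytic kernel in place of a clinical
dose algorithm, and no robust optimization.  Passing tests therefore
demonstrate that the evaluation machinery (indices, bandwidths, delivery
timing, phase assignment, accumulation, statistics) is correct, and that
group contrasts have the expected direction on synthetic patients; they do
not reproduce the published per-patient dosimetric medians, which depend on
the 20 real anatomies.
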