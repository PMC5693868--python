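# Methods

This note documents the model, the parameter defaults and the numerical
choices behind `furrowsim`, in the spirit of a methods supplement: what is
assumed, what is calibrated, and what the tests do and do not demonstrate.

## Geometry

The embryo cross-section is a ring of `n_cells = 84` quadrilateral-sector
cells between the rigid vitelline circle (`R_v = 20` length units; one unit
is roughly 5 µm for a ~100 µm embryo radius) and the yolk (inner radius
13).  These radii give columnar initial cells of height 7 and apical width
~1.5 (aspect ~4.7:1, in the columnar range observed at gastrulation onset).
The apical surface starts in contact with the vitelline circle (gap 0).

Each cell membrane is subdivided into 5 sections per lateral side and 3
sections on the apical and basal sides.  Lateral membranes are shared
between neighbours (one node set per boundary ray); apical/basal interior
subdivision nodes are private per cell, making the ring watertight by
construction.  The membrane subdivision induces a 5 × 3 grid of
quadrilateral sub-regions per cell — the 15 viscous finite elements.  A
boundary-only triangulation cannot produce 15 triangles from the 16-gon
cell outline (triangle counts of a polygon triangulation have fixed
parity), so the grid reading is the only self-consistent one.

Interior grid points are *not* degrees of freedom: they are fixed Coons
(transfinite) blends of the 16 boundary nodes, and each element quad is
split into four constant-strain-rate triangles by a fan around its corner
average.  The 4-fan is invariant under reflection; a single-diagonal split
would bias the viscous operator chirally and break the left/right mirror
symmetry of the dynamics at the 1e-3 level per simulated minute.

DV domains default to |θ| ≤ 25.8° central mesoderm (13 cells), ≤ 38.6°
lateral mesoderm, ≤ 47.2° mesectoderm, ectoderm beyond.  The published
cross-sections show these only as colour bands, so the cutoffs are
approximate and configurable.

## Force schedules

Edge tensions are normalized per unit viscosity to [0, 1]; the wild-type
maximum of exactly 1 is attained on apical edges at the ventral midline.
Spatial shapes (all symmetric in θ and normalized to unit maximum):

* apical — Gaussian `baseline + amplitude·exp(−(θ/30°)²)`, baseline 0.05;
* lateral — logistic plateau `1/(1 + exp((|θ| − 45°)/4°))`, ≥ 0.99 of its
  maximum over the whole central mesoderm, ~0 dorsally;
* basal — `0.25 + 0.75·(1 − exp(−(θ/60°)²))`, maximal in the ectoderm and
  fading smoothly toward the ventral midline.

Time courses are piecewise-linear keyframe lists.  Wild type (duration 21
min, the time at which invagination completes): apical 0.05 → 1.0 at 12 min,
held; lateral 0.02 → 0.30 over 16–21 min; basal 0.02 → 0.12.  The furrow is
therefore mostly apical-driven, with lateral contraction arriving late to
internalize the mesoderm — orderings chosen so the three headline series
(constriction, invagination, lengthening) reproduce the wild-type shapes.
No numeric table of amplitudes is published for the force distributions being re-parameterized;
all values here are approximate re-parameterizations exposed in the config.

*neur*-like (45 min): apical peak 0.6 (60% of wild type) reached at 24 min
(time-to-peak doubled); lateral keyframes delayed by +26 min.  The delay is
deliberately larger than a first guess of a few minutes: with a short shift
the run internalizes fully and ventral cells re-shorten before the end of
the window, inverting the lengthening comparison that defines the
phenotype.  With +26 the run ends mid-invagination with elongated ventral
cells — delayed invagination and increased lengthening, as required.

*Brd*-like (35 min): the wild-type mesoderm schedule plus a dorsal-centred
Gaussian (width 60°) of ectodermal apical tension ramping linearly from 8
min.  Its amplitude is solved at build time so the total apical force at
θ = ±180° equals the total at θ = 0° exactly at the parity time (21 min);
past parity the ramp continues at the same slope, capped at 1.  Evaluated
forces are clipped to [0, 1].

`symmetrize_regularize` mirrors a tabulated profile about θ = 0 and applies
a circular moving average (default window 10°); both operations are
total-variation non-increasing, which is the property the tests check.

## Solver

Nodal velocities solve the saddle system

    [ C  Jᵀ ] [ v ]   [ F ]
    [ J  0  ] [ λ ] = [ 0 ]

with `C` the assembled triangle viscous operator (dissipation
`2 μ Σ A (ε_xx² + ε_yy² + 2 ε_xy²)`) plus a small per-node drag
(`0.05 μ`) that removes the rigid-body null modes, and `J` stacking the
per-cell area-rate constraints and the active vitelline contacts (radial
velocity of touching nodes).  Contacts are one-sided: an active-set loop
releases nodes whose multiplier would make the wall pull.  Constraint
reactions therefore enter the force balance directly; the explicit
projections (`vitelline_contact`, `enforce_incompressibility`, a radial
clamp and a Newton projection onto the constant-area manifold) run after
each step only to remove the O(Δt²) drift.  A force-only step followed by
projections — the obvious alternative — is unstable here: the pressurized
yolk then drives large unbalanced velocities because nothing in the
velocity solve represents the wall reaction.

Edge tensions act as equal-and-opposite pulls on edge endpoints; shared
lateral edges take the mean of the two adjacent cells' lateral values.
Yolk pressure is applied as an outward traction on the basal boundary loop.

Units and calibration.  Schedule values are dimensionless; the solver
multiplies them by `force_scale = 10` (physical tension per unit normalized
force).  This constant sets the clock — normalizing forces per unit viscosity fixes
only their ratios, and the absolute scale is implied by matching the movie
timeline (invagination complete at ~21 min).  The
initial yolk pressure `P0 = 0.40` is the second calibration: the pressure
may deviate at most ±10% from it, so its magnitude is what pins the
epithelium to the shell dorsally while still allowing the ventral apical
surface (Laplace pull ≈ tension/R_v) to detach and fold.  With gain k = 2
the wild-type run keeps the yolk area within 1.5% and the pressure within
3.1% of initial — inside the 6% and 10% bands without ever invoking the
pressure clamp.  The yolk interior is treated as a hydrostatic reservoir
(pressure only); its viscosity is not discretized.

Numerics: Δt = 0.01 min (output every 1 min, the movie cadence);
incompressibility tolerance 1e-6 relative (observed drift ≤ 1e-12 after
projection); contact tolerance 1e-8.  Element areas in the viscous assembly
are floored at 5% of their initial value so that strongly sheared cells —
whose interpolated interior triangles can fold even while the cell boundary
stays simple — keep a positive-definite operator; cell areas themselves are
always evaluated on the true boundary polygons.  Time integration is first
order: halving Δt changes final node positions by ≈0.8% RMS (normalized to
the embryo radius) over a smooth six-minute window on a coarse 28-cell
ring; through a buckling event trajectories of any integrator separate
faster, so the consistency check is defined on smooth dynamics.

## Observables

* apical constriction — summed apical polyline length of central-mesoderm
  cells, normalized to t = 0 (cell cross-section areas are conserved by
  construction and carry no signal);
* invagination depth — radial drop of the ventral-most cell's apical
  arc-length midpoint below the vitelline circle, / R_v (0 at initial
  contact; midpoint rather than deepest vertex for robustness to kinks);
* ventral lengthening — mean central-mesoderm cell height (apical-to-basal
  midpoint distance) over mean height of ectoderm cells within 30° of the
  dorsal midline;
* aspect ratio — major/minor axis of the second-moment (best-fit) ellipse
  of the cell polygon (bounding-box ratio is available via the tracked-cell
  tables if preferred);
* DV constriction gradient — least-squares slope of per-cell relative area
  change against |DV position|, per time point (regression rather than
  binning; the choice is flagged because the original definition is not
  published in the main text).

## Pulse pipeline

Pools: the medial region is the cell mask eroded three times with the 3 × 3
cross (4-connectivity, as ImageJ's binary erode), giving a 3-px junctional
band along straight boundary segments; junctional = total − medial exactly.
Traces: max z-projection, optional rolling-ball background subtraction
(radius configurable), per-cell
mean intensity, normalization to the mean of the first 3 samples (the
signal before apical recruitment).  Segmentation: local maxima of a
moving-average-smoothed copy (window 3) with minimum prominence 0.1
(normalized units); boundaries at the intervening minima, one peak per
segment, no multi-peak deconvolution.  The prominence default is nonzero
because at 0 camera noise splits single pulses into duplicate segments —
5× the default noise floor and far below the amplitude threshold.
Fitting: `a0·x + b0 + a1·exp(−((x − b1)/c1)²)` by bounded least squares
with rule-based (deterministic) initialization; bounds confine the fit to
identifiable peaks (c1 between one sample spacing and the segment span,
centroid inside the segment) since narrower or wider "peaks" are
indistinguishable from noise or background.  Filtering: discard iff
`a1 < 0.25 ×` initial value — the boundary case is retained, since only
strictly smaller amplitudes are excluded.  The whole pipeline is
deterministic given its inputs.

## Synthetic data

The trace generator draws, per cell, a Poisson pulse count (default mean
2.4 — the wild-type ventral regime; a rounded-Gaussian alternative matches
reported count SDs, e.g. 4.5 ± 2.2 for the over-expression regime), pulse
amplitudes 0.4–1.2 × the initial value, widths c1 of 2–4 samples at the
12-s cadence, a linear background, and additive Gaussian camera noise (SD
2% of the baseline).  Centroids keep a minimum separation of 8 samples
(~96 s), reflecting sequential assembly–disassembly cycles; unplaceable
pulses are kept but flagged `crowded`, as are any centroids closer than 2
samples.  What passing recovery tests show is that the pipeline recovers
the programmed statistics when pulses are resolvable at the imaging
cadence; they do not certify behaviour on overlapping pulses, drifting
baselines beyond linear, or segmentation errors upstream of the mask.

The scene generator tiles square cells separated by 1-px membrane lines and
paints the myosin channel with independent junctional (3-px band by taxicab
distance to the boundary) and medial intensities; cells smaller than 7 × 7
px are rejected (no medial pool survives three erosions).  The area-table
generator produces a collective regime (every cell constricts from t = 0,
final loss graded linearly to ~0 at the domain edge) and an asynchronous
regime (a random half constricts at random onsets), matched in cohort-mean
final constriction so that only the spatial organisation differs.

## Known limitations

* No cell rearrangement, division, or 3D effects; no self-contact between
  cell boundaries, so fully internalized mesoderm can overlap and its
  late-time apical measures are not meaningful — observables are read
  up to invagination completion.
* The mirror-symmetry invariant holds to machine precision for smooth
  dynamics; through buckling, rounding asymmetries grow chaotically, as
  they would in any symmetric unstable system.
* Force magnitudes, domain extents and schedule timings are approximate
  re-parameterizations; all are exposed in the run config.
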