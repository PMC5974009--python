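# Methods

## Volume model

The blood-pool volume of the left ventricle at one cardiac phase is the
slice summation `EV = Σ_slices |area| × slice thickness`, with in-plane
areas in mm², thickness in mm, and a single mm³→ml division by 1000 inside
the volumetrics module. Slice thickness is the default integration weight
(`spacing_mode="thickness"`), which treats the stack as contiguous; a
`z_spacing` mode that weights by the midplane spacing is available for
gapped or overlapping stacks. No partial-volume weighting is applied at the
most basal included slice.

Coordinates are physical millimetres in-plane; z is the slice midplane
position along the long axis and decreases toward the apex. Base/apex
ordering is always derived from z, never from slice numbering, so layer
assignment is invariant to how slices happen to be indexed.

## Preprocessing

Slices flagged `mitral_valve_visible` or `beyond_lv` are removed together
with their contours; at least three slices must remain (three layers must
be formable). Misalignment correction fits, per phase, a straight
long-axis model — ordinary least squares of the endocardial centroid
(x, y) on z — and translates each slice's contours so the centroid lands on
the fitted line. Translation cannot change a polygon's area, so alignment
is provably volume-neutral; this is asserted in the tests at 1e-12
relative (floating-point shoelace sums of translated vertices are not
bit-identical). The straight-axis model is a design choice: it is the
simplest model that removes independent per-slice offsets exactly, and for
a ventricle whose true axis is straight the post-alignment centroid
residuals vanish to rounding.

## AHA segmentation

Included slices, ordered base→apex, are split into three contiguous groups
by slice count: for n = 3q + r the remainder goes one slice to basal, then
one to mid. Count-based thirds (rather than long-axis-distance thirds) are
used because they are well defined for any stack, including uneven
coverage; the alternative was left unimplemented. Each contour is divided
about its area centroid into six 60° sectors (basal, mid) or four 90°
sectors (apical), counterclockwise from the per-study anterior reference
direction, numbered anterior-first: 1–6 basal, 7–12 mid, 13–16 apical. The
centroid anchor and the external reference angle are design choices: the
centroid is the standard anchor for polar maps, and automatic detection of
the RV insertion requires long-axis images that are out of scope. Segment
17 (apical cap) has no short-axis blood pool and is excluded.

Sector areas are computed by clipping the polygon against each wedge. A
wedge of ≤ π opening is the intersection of two half-planes, so two
successive Sutherland–Hodgman clips suffice; the clips are vectorized and
exact up to rounding. Adjacent wedges share the same boundary ray and
therefore the same computed edge intersections, which is why the 16 sector
areas sum to the full polygon area to ~1e-15 relative — asserted at 1e-9 in
property tests over random star-shaped polygons. The global volume is
computed independently from the unclipped polygon areas, so this
conservation check is a genuine test of the clipping partition, not a
restatement of the definition.

## Function indices

EDV is the maximum of the global curve and ESV the minimum, ties breaking
to the earliest phase. Defining EDV as the curve maximum rather than "the
volume at phase 0" is deliberate: with ECG-gated cine the first phase
normally is the maximum, so the definitions coincide on well-formed data,
and the maximum is robust to trigger offsets. SV = EDV − ESV,
EF = SV/EDV · 100; a constant curve yields SV = EF = 0 (valid, not an
error). The time to maximal contraction is the phase time of the curve
minimum as a percentage of the cycle; phase i defaults to
i · cycle/n_phases when explicit phase times are absent.

## Phantom

The phantom is the package's validation instrument: a half-ellipsoid
ventricle truncated at the base plane, long axis L fixed over the cycle,
contraction purely radial, so V = (2/3)πr²L inverts to
r(t) = √(3V(t)/(2πL)). The prescribed curve is a raised cosine between EDV
and ESV, time-warped so the minimum falls at `es_fraction` of the cycle.
Defaults (EDV 160 ml, EF 40%, L 90 mm, 10 × 8 mm slices, 20 phases over
1000 ms, end systole at 35%, 400 vertices per contour, one mitral slice,
wall thickness 10 mm, no noise, seed 17) describe a mildly dilated
ventricle imaged with a routine SA cine protocol; EF 40% sits between the
severely depressed CRT candidate (≤ 35%) and the healthy volunteer range so
that both regimes are a small parameter change away.

Slice k's midplane lies (k + ½) × thickness below the base; the contour
radius follows the ellipsoid profile r(t)·√(1 − (d/L)²) with d the depth
below the base, tapering to zero toward the apex. Ground truth is the
midpoint-rule analytic slice sum over the *included* slices — truth and
pipeline integrate the same grid, so their comparison isolates the polygon
discretization (O(1/n²) in vertex count: a regular n-gon underestimates
the circle by 2π²/3n², ≈ 4·10⁻⁵ at 400 vertices), while
`analytic_volume` provides the continuum value separately. Because
contraction rescales all radii equally, the slice-sum EF equals the
prescribed EF exactly on any grid — provided the end-systolic time lands on
the phase grid (0.35 × 20 phases does); off-grid `es_fraction` biases the
sampled minimum slightly high and EF slightly low, which is a property of
sampling, not an error.

Noise is per-vertex radial Gaussian jitter; since vertices stay at sorted
angles about the centre with positive radii, noisy contours remain simple
(star-shaped) for any noise level that keeps radii positive. Misalignment
is a per-slice in-plane offset held constant across phases, as for
breath-hold misregistration. Draw order from the single seeded generator
is fixed (offsets per slice, then per-vertex noise phase-major, endo before
epi), so identical specs give byte-identical studies. The phantom does not
emulate papillary muscles, trabeculation, regional wall-motion
abnormalities, through-plane motion, a curved or tilted long axis, or
segmentation failure modes; passing phantom tests therefore demonstrates
the correctness of the integration, sectorization and statistics, not
robustness to real segmentation error.

## Agreement statistics

Pearson r uses the exact two-sided p from t = r√((n−2)/(1−r²)) on n−2 df;
regression is OLS of method B on method A with R² = r² (defined as 0 for a
constant response). Bland–Altman differences are d = x − y with x the
system under test; limits are bias ± k·SD(d) with the n−1 SD and k = 1.96
by default — 1.96 reproduces the conventional 95% limits, and k is a
parameter for users who prefer ± 2 SD. The CoV is SD(d) over the pooled
mean of all measurements of both methods, the standard method-comparison
reading of "SD/mean"; the denominator is switchable to the method-A mean.
Curve agreement computes per-subject Pearson r between equal-length global
curves (resampling unequal grids is deliberately the caller's problem, and
unequal lengths raise an error naming the subject), summarized by
linear-interpolation (type-7) median and Q3−Q1, plus the mean ± SD of the
absolute per-subject time-to-minimum differences in percentage points.

## Numerical choices and limitations

JSON studies serialize with sorted keys and Python's shortest round-trip
float repr: byte-stable and lossless. Curve CSVs use %.9g floats (contract:
re-read to 1e-6 ml). Polygon validity (simple, positive area) is checked
with shapely at load/save; the analysis pipeline itself is pure
numpy/scipy. Angular interval bookkeeping is half-open [θ0, θ1), so
boundary vertices contribute zero-area slivers at most. Degenerate inputs
raise typed errors (schema vs geometry) naming the offending slice, phase
and role.

Test and validation problem sizes — 10–50 slices, 20 phases, 400–2000
vertices for recovery tests; 200 slices × 2000 vertices for the continuum
oracle; 100 randomized phantoms for conservation; 10⁷–10⁸ Monte-Carlo
samples for geometry oracles — were chosen so the discretization error
under test is at least an order of magnitude above the oracle's own error
while the full suite runs in about a minute.

Out of scope by design: image segmentation and mask ingestion, myocardial
mass and wall thickening (the epicardium is generated and carried through
alignment but unused in volumes), scar quantification, intraclass
correlation and repeated-measures Bland–Altman, and interpolation of
curves to continuous time.
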