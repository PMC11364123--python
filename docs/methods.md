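# Methods

This note documents the models, conventions and numerical choices behind
`complexiqa`, in the order data flows through the package.

## Plan model and conventions

A plan is a list of dynamic-MLC beams; a beam is an ordered control-point
(CP) track with cumulative meterset fractions (non-decreasing, 0 → 1), two
MLC bank position arrays in mm (bank A is the larger-coordinate side, so
the leaf-pair gap `a − b` is ≥ 0; a 1e-6 mm tolerance absorbs vendor
round-off on closed pairs), jaw windows, a meterset in MU and a dose rate
(default 400 MU/min when a file omits it).  Only sliding-window (dynamic)
beams are modelled; static and setup beams are excluded on read.  At fixed
dose rate the meterset fraction defines the time axis: interval *n* lasts
`Δt_n = Δcmf_n · MU / rate`.  Zero-meterset intervals would make leaf speed
undefined and are rejected rather than merged.

## Kinematics and the dynamics metrics

Leaf speed over an interval is |Δposition|/Δt (cm/s, both banks stacked
along the leaf axis); acceleration is the speed change between consecutive
intervals over the centred time step (no values at the track endpoints).
A leaf-interval counts as *moving* above 1e-4 cm/s so parked closed leaves
do not dilute the speed statistics.  Leaf travel (LT) is aggregated two
ways — mean over leaves that move at least once, and sum — because both
conventions are used in practice; both are registered as separate metrics.

The modulation indices MI_s and MI_a integrate, over f ∈ [0, 1] on a
1000-node trapezoid grid, the weighted fraction Z(f) of inter-CP **speed
variations** (|Δ speed|; |Δ acceleration| for MI_a) exceeding f·σ, where σ
is the standard deviation of the moving-leaf speed (acceleration) series.
Counting the *changes* against the *series'* σ makes the index respond to
erratic motion rather than to motion per se: constant-speed delivery gives
exactly 0, smooth sweeps give small values, stop-and-go sweeps large ones.
The weight w(v) = 1 + v/(3σ) doubles the weight of a variation five times
larger than σ (e.g. 0.5 vs 0.1 cm/s when σ = 0.1 cm/s); the slope is
configurable, and unweighted variants are registered alongside.

## Aperture metrics

The per-CP aperture is the set of jaw-clipped open leaf-pair intervals.
Area and the staircase perimeter are computed exactly from the segments;
the edge area metric (EAM, open-area fraction within a 5 mm penumbra
margin of any aperture edge) and the fallback converted aperture metric
(CAM, mean of exp(−d/κ) over open points, κ = 5 mm) are computed on a
0.5 mm raster using a Euclidean distance transform with a half-pixel
boundary correction, which makes grid-aligned rectangles exact (a 100 mm
square with a 5 mm margin gives EAM = 0.19 identically).  The raster is
cropped to the open-aperture bounding box plus two pixels — every open
cell's nearest background cell lies inside that window, so distances are
unchanged while narrow sliding windows rasterize cheaply.

MCS follows the canonical leaf-sequence × aperture-area construction:
LSV per CP from adjacent-leaf edge differences normalized by the bank's
position range over open pairs, AAV as CP area over the beam's per-pair
maximal opening, combined MU-weighted.  Control-point MU weights are
interval-averaged, `w_j = (ΔMU_{j−1} + ΔMU_j)/2`, which sums to the beam
meterset and makes every MU-weighted aperture statistic exactly invariant
under duplicating a CP with its meterset split in half.  Dynamics metrics
live on interval *boundaries*; any CP-track refinement changes their
variation multiset, so the duplication invariance deliberately covers the
aperture and MU families only.

Exact published formulas for CAM and MAD are not fully specified in the
open literature; both ship as documented fallbacks (flagged `fallback` in
the registry): CAM as above, MAD as the MU-weighted mean distance of open
pair midpoints from the aperture centroid.

The registry holds exactly 53 metrics (24 aperture, 8 MU, 21 dynamics).
Each entry declares an orientation: +1 if larger values indicate a more
complex plan, −1 for the opposite, 0 for structural bookkeeping quantities
(beam count, union field area, …) or metrics whose response to the
generator's single complexity dial is genuinely sign-ambiguous under this
generator (LSV, unweighted MI_a).  Orientations were derived from the
generator's construction and verified on a dial-gradient cohort; a note on
the staircase geometry: the isoperimetric "irregularity → 1" limit does
not apply to Manhattan perimeters (a rasterized disc's staircase perimeter
converges to 8R), so the irregularity tests use the exact square closed
form 4/π instead.

Plan-level values are MU-weighted means over beams (totals add).  Whether
published studies pool CP data across beams or aggregate per beam is
generally unstated; the per-beam MU-weighted choice is documented here and
applied uniformly.

## Detector layouts and the gamma engine

The helical array places 66 diodes per ring (10 mm arc pitch on a 105 mm
cylinder) on 21 rings at 10 mm axial pitch over a 210 mm length — 1386
diodes, rings staggered by half the angular pitch; the count, radius and
pitch are the modelled facts, the vendor's exact spiral is not reproduced.
The cross layout is two perpendicular 200 × 200 mm planes through the
cylinder axis with 5 mm pitch inside the central 60 × 60 mm and 10 mm
outside, axis-line points deduplicated; this idealized lattice has 1095
points, close to but not equal to the commercial device's 1069 (its exact
diode pattern is not published).  The oblique variant is the same lattice
rotated 45° about the axis.

Gamma is global (dose differences relative to the maximum of the reference
distribution by default; configurable), with a 10% dose threshold and the
reference points — detector readings for MQA, planned-dose samples for CQA
— never interpolated or smoothed.  Only the evaluated grid is interpolated
(trilinearly).  The search runs over displacement shells of a lattice with
step min(DTA)/10 and per-criterion radius 3×DTA, with early termination
(a point leaves the search when no farther shell can improve it), followed
by a local refinement on a step/5 sub-lattice around each point's best
offset.  All criteria analysed together share one candidate set, and each
point's refinement candidates are evaluated for every criterion, so a more
lenient criterion can never score below a stricter one on the same dose
pair — the GPR ordering across 3%/3mm → 1%/1mm is exact by construction,
not a discretization accident.  Against an exhaustive 0.1 mm dense search
the worst-case |Δγ| on random smooth fields is ≈ 0.01; pass/fail uses
γ ≤ 1 + 1e-9 to absorb float round-off at the exact boundary.  The search
radius only affects gamma *values* above ≈ radius/DTA, never pass/fail
(a passing point's minimizer lies within DTA), so scaled-down runs may
shrink it safely.

## The synthetic cohort

The generator emulates a two-linac, site-stratified sliding-window IMRT
service.  One dial m ∈ [0, 1] controls modulation:

* mean leaf gap interpolates log-linearly from the full field width at
  m = 0 (a near-static open field) to 4 mm at m = 1, so small-aperture
  content ramps in over the upper dial range;
* multiplicative gap noise (σ up to 0.45, rate-capped at 12 mm) and ±6m mm
  inter-leaf stagger, both smoothed over a correlation time that shortens
  from 2.5 s to 1.5 s as m grows (complex plans have rougher speed
  profiles);
* meterset per prescribed Gy grows as 250·(1 + 0.8m) MU/Gy;
* the window centre sweeps at constant speed in delivery time; leaf speeds
  are capped at 2.5 cm/s, with regeneration (more CPs, fresh noise) on cap
  violations.

Site profiles set beam counts (head-and-neck 7–9, chest/abdomen and pelvis
5–7, limbs 2–4) and field sizes; the MLC is a 60-pair Millennium-style
bank (40 central 5 mm leaves, 20 outer 10 mm).  Prescription is 2 Gy per
fraction at 400 MU/min.

The toy dose engine accumulates per-interval open-aperture fluence
(midpoint leaf positions, fractional cell coverage) on a 2.5 mm grid in
the beam's-eye (x, z) plane, convolves with a 3 mm Gaussian penumbra,
extrudes along the beam axis y with mild exponential attenuation
(0.002/mm), stacks beams and scales the grid-centre dose to the
prescription.  The beam axis is perpendicular to the detector-cylinder
axis, so the helical diodes sample in-field dose as in a composite
delivery.  It is not a physical dose calculation: no heterogeneity, no
scatter kernels, no leaf-end or tongue-and-groove transmission.

Two error channels with frozen default coefficients define the QA
surrogates:

* **Calculation channel** (deterministic): extra fluence-plane blur of
  8 mm × SAS₅ and an output offset of 5% × SAS₅.  The collapsed-cone
  variant adds an output mismatch of 0.05% per mm of |mean gap − 10 mm|
  (capped at 20 mm) — a beam model tuned with a single leaf-gap correction
  misrenders plans whose gap content sits far from its calibration point,
  which is non-monotone in complexity by construction.
* **Measurement channel** (stochastic, seeded): each leaf gets a
  persistent positional error with σ = 0.6 mm per cm/s of its mean speed
  plus white per-CP jitter at the same coefficient, scaled by a per-plan
  lognormal delivery-quality factor (σ = 1.3) — equally complex plans are
  delivered under different daily machine conditions; both banks also
  shift outward by 0.1 mm (a 0.2 mm gap-widening calibration error), and
  readings get 0.4% i.i.d. detector noise.

These defaults were calibrated once, before the test expectations were
frozen, so that the default cohort's 2%/2mm GPRs span roughly 70–100%,
the dynamics–MQA correlations are negative in every cell and pooled
strongest at 1%/1mm, the aperture–CQA correlations are negative for all
three calculation systems, and every calculation-vs-measurement
cross-correlation stays below the moderate cut.  Because a single dial
drives both channels, that last property is achieved through plan-level
delivery-quality randomness, not by removing the shared complexity driver
(which would also erase the aperture–CQA signal).  The default cohort is
200 plans with the clinical site proportions (75 on the four-system linac,
125 on the two-system linac); the full 404-plan structure is available via
`CohortConfig.study_counts()` and is used for the bookkeeping checks,
which do not require dose simulation.  Cohort gamma runs use subsampled
layouts (every 5th diode), a DTA/5 search step and a 1.5×DTA radius as the
package's scaled problem size; GPR pass/fail is unaffected by these
choices (see above).

What passing the recovery tests does and does not show: the statistics
stage demonstrably recovers sign and criterion-ordering structure injected
by a known mechanism at realistic noise levels; it says nothing about the
magnitudes of complexity–QA correlations in clinical data, which depend on
multidimensional plan populations, real dose engines and real detectors
that the surrogates deliberately do not model.

## Statistics

Spearman correlations are tie-corrected with two-tailed t-approximation
p-values (n is tens to hundreds; p < 0.05 two-tailed is the significance
convention; no multiple-testing correction, matching common reporting —
a Holm option exists but is off by default).  Strength grades partition
|r| as [0.7, 1] strong, [0.5, 0.7) moderate, [0.4, 0.5) weak, [0, 0.4)
none; the half-open choice at 0.5 and 0.7 is documented here since verbal
definitions typically overlap at the boundaries.  Constant inputs raise
rather than return NaN silently; empty or non-overlapping cells in the
correlation grids are emitted with explicit status markers, never dropped.

PCR standardizes the metric matrix (correlation-matrix PCA — the metrics
have incommensurate units), keeps the smallest number of components whose
cumulative explained variance reaches 90%, and fits GPR on the component
scores by ordinary least squares, reporting R² and the overall F-test p.
Zero-variance columns are dropped with a warning; duplicated (collinear)
columns change nothing, which is the point of regressing on components.
The report stage runs PCR per system/criterion stratum (and per site where
populated) rather than pooled, and writes plain CSV plus a Markdown
summary; reruns on the same table regenerate the files bitwise.

## Known limitations

* The dose engine and QA surrogates are structural emulations; absolute
  GPR levels have no clinical meaning.
* The 53-metric registry covers the canonical families; individual
  supplementary definitions from specific studies may differ in detail
  (CAM/MAD fallbacks are flagged).
* The cross-array layout is an idealized lattice (1095 vs the device's
  1069 diodes).
* Gamma values far above 1 are search-radius-limited (documented; pass/
  fail is unaffected).
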