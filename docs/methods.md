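# Methods

`darkfleet` estimates the size and length distribution of a non-broadcasting
("dark") vessel fleet from two data streams: an AIS position feed and a set
of satellite-radar (SAR) scenes with point detections and radar-estimated
lengths. The method has four stages: empirical movement rasters, probabilistic
AIS–SAR matching, detectability and length-error models, and a histogram
deconvolution with bootstrap uncertainty. This note records the model, its
assumptions, the numerical choices, and what the synthetic test worlds do and
do not demonstrate.

## Movement probability rasters

For each of six vessel classes, six speed bins (centres 1, 3, 5, 7, 9,
12.5 kn) and 36 signed time offsets (±0.5 … ±448 min) — 1296 keys in all — a
raster records where vessels of that class historically ended up relative to
a straight-line extrapolation of a known position. The frame is centred on
the dead-reckoned point (speed × elapsed time along the course over ground),
with +x along the course and +y to port. Grids are 1000×1000 by default, with
pixel width max(1, Δm)/1000 km, so the raster always spans max(1, Δm) km:
1 km wide with 1 m pixels below one minute, 10 km wide with 10 m pixels at
ten minutes. Values are probability per km²; every raster integrates to 1.

Construction: every ordered ping pair within ±530 min contributes one
displacement sample, keyed by the first ping's class and speed bin and the
signed gap, assigned to the offset bin nearest in log-|Δt|. Counts are
histogrammed, optionally blurred (below), and divided by (sample count ×
cell area).

Numerical choices:

* **Bin edges.** Speed-bin edges at 0, 2, 4, 6, 8, 10, ∞ kn (midpoints of
  the centres, open top). Offset bins by nearest centre in log space, sign
  preserved. Pairs with zero gap or |Δt| > 530 min are not used for training;
  at match time the offset is clamped to the outermost bin.
* **Smoothing** (`smooth_px`, default 1 pixel). Training sets of desk scale
  produce patchy point-cloud histograms; the cell-wise product of two patchy
  rasters can be zero even when the vessel's position is perfectly
  consistent. A σ = 1 px Gaussian blur of the count histogram (renormalized)
  restores contiguous support while widening the distribution by about one
  pixel. Set 0 to reproduce raw histograms.
* **Sparse keys** (`min_samples`, default 500). A key with too few samples
  borrows the grid of the same class at the nearest trained speed bin, then
  class "other", then any class at that offset; if nothing at that offset is
  trained, an isotropic Gaussian with σ = 15 % of the half-width stands in.
  Borrowed and stand-in rasters are flagged `sparse`.
* **Grid resolution** (`n_pixels`). The raster extent is fixed by the pixel
  formula; `n_pixels` only sets how finely it is divided. Pipeline runs on
  synthetic data use 150 px; worked-example assertions use the full 1000.
* **Projection.** All frames are local azimuthal-equidistant tangent planes
  on a spherical Earth (R = 6371 km); at raster scales (≤ 448 km) and for
  the 200 nmi candidate gate, projection error is negligible relative to the
  quantities involved.

## Matching AIS vessels to radar detections

Candidates for a scene are non-gear tracks with at least one ping within
12 h and 200 nmi of the footprint. Gear beacons (MMSI starting 1, 8 or 9;
buoy/voltage names — the name patterns are configuration, since no public
authoritative vocabulary exists; explicit `gear` class) are removed
up front, with a diagnostic audit (`gear_match_audit`) reporting whether any
slow-moving gear would have matched a detection.

For each candidate, the latest ping at or before the scene time and the
earliest after it anchor one raster each (a ping exactly at scene time counts
as the before side; the choice only fixes determinism). Both rasters are
resampled onto a shared east/north grid at the finer pixel width and fused:

* closest ping within 10 min of the image — weighted average, each raster
  weighted by Σp²·da (concentrated evidence counts more). Near-simultaneous
  pings carry nearly duplicate information; multiplying them would just
  square the density.
* otherwise — cell-wise product, renormalized. The product needs only the
  intersection of the two supports, which keeps grids small; a disjoint
  intersection means the track contradicts itself at the scene and the
  vessel is excluded from matching (logged).
* one-sided evidence is used as is.

The common grid is capped at 2×10⁶ cells (the pixel is coarsened past that),
a cost bound that matters only when a sub-10-minute raster meets a
multi-hour one.

The in-scene probability of a vessel is the always-multiplied fused density
summed over cells whose centres fall inside the footprint. Vessels above
0.95 are treated as inside, below 0.05 as outside (and excluded), between as
uncertain.

The score of a vessel/detection pair is the fused density at the detection
point (bilinear). Matching is greedy on the score matrix: accept the global
maximum, delete its row and column, repeat until the best remaining score
falls below the threshold. The default threshold is 2.5×10⁻⁵ vessels/km²
inside a configurable analyst band of 5×10⁻⁶–1×10⁻⁴; the same quantity can
be derived from fitted densities as (d_d·p_d + p_f)/p_d, the level at which
a detection is more likely a dark vessel or false alarm than the candidate.
Exact ties break by smaller vessel id then detection id. A match with a
competing score within a factor of 100 in its row or column is flagged
ambiguous — kept, but reported, so match counts come with a low/high range
instead of a manual review.

## Detectability and length error

**Detection curve α** (1 m bins over 0–400 m). Per-vessel detection
fractions (matched appearances over confident in-scene appearances) are
regressed on true length with a τ = 0.5 quantile regression below the 60 m
knot, clipped to [0, 1] and to non-decreasing; at and above the knot, α is
the pooled detection rate of the large vessels. In the regime these models
emulate the ramp runs from ~20 % at 20 m to ~90 % at 60 m with a plateau
near 0.91. The median regression approximates the mean rate only when
fractions are reasonably fine-grained — with one or two appearances per
vessel the median of a Binomial fraction is biased low wherever the rate is
below ½, which propagates directly into the deconvolution (see the
synthetic-world notes below).

**Length-error matrix L** (400×400). Quantile regressions at τ = 1/3 and
2/3 of radar length on true length (linear by default, degree exposed)
define, at each true-length bin centre, a lognormal via the closed form
μ = (ln q₁₃ + ln q₂₃)/2, σ = (ln q₂₃ − ln q₁₃)/(2 Φ⁻¹(2/3)). Column j is
that lognormal integrated over 1 m radar bins and renormalized, so L is
column-stochastic and applying it conserves counts exactly. If the fitted
quantile lines cross inside the data range they are refitted as a
location-shift model (common median slope, intercepts from residual
quantiles), which cannot cross; a warning is emitted.

## Dark-fleet deconvolution

With ℓ_A the unknown true histogram, the expected radar-length histogram is
ℓ_E = L(α ⊙ ℓ_A). The estimator minimizes

    O(ℓ_E, ℓ_o) = max |C_E − C_O| + (T_E − T_O)²

over non-negative ℓ_A, where T is the total, D = ℓ/T and C = cumsum(D):
a Kolmogorov–Smirnov term for shape plus a squared-count term for
magnitude. The squared term is dimensionally dominant for large fleets (a
10-count miss costs 100 against a KS term bounded by 1); it is implemented
verbatim rather than reweighted.

The KS term is non-smooth, so the search is derivative-free projected
coordinate descent over a coarse parameterization: ℓ_A is constant on 5 m
blocks (80 values), which regularizes the inversion; per-coordinate moves
(multiplicative ±50 %, additive ± a decaying step, and zero) update ℓ_E in
O(400) via precomputed block columns. The naive inverse ℓ_o/α (where
α > 0.02) seeds the search; 8 restarts (2 inside the bootstrap) jitter the
seed lognormally. Everything is deterministic given the seed. Observed mass
in radar bins that the forward model cannot reach (Lα ≡ 0 there) raises an
explicit unidentifiability error naming the bins.

The fishing share of the dark total is taken from the AIS census among
vessels under 60 m, on the assumption that dark vessels and broadcasting
vessels have the same fishing/non-fishing mix at those lengths.

**Bootstrap.** α and L are refitted on a random half of the confident
in-scene vessels; the held-out vessels' matched detections are treated as an
observed histogram and the estimator predicts the held-out instance count.
The distribution of estimated/true ratios over many experiments gives a mean
absolute percent error and the 5th/95th-percentile multipliers used to dress
point estimates with a 90 % interval. A 10,000-experiment setting
experiments is available; pipeline defaults use 200–300, and the test suite
60–300, which is enough to place the MAPE (≈ 8 % on the default synthetic
world, with CI coverage ≥ 80 % over repeated worlds).

## Coverage planning

Activity hours are gridded into half-open 4°×4° cells × 52 calendar weeks
(7-day blocks from 1 January, remainder folded into week 52). Cells are
selected in decreasing-hours order (ties by cell index) until the target
fraction of total activity is covered; for this separable objective the
greedy order is exactly the minimum-cardinality selection, and the test
suite checks it against exhaustive subsets. Both denominators — occupied
cell-weeks and all cell-weeks — are reported, since "fraction of cells"
is ambiguous between them.

## The synthetic worlds

The generator emulates the statistical structure the models assume, with
known ground truth:

* Correlated-random-walk movement (per-minute Gaussian heading innovations,
  AR(1) speed around a class cruise speed) with a home-range term: beyond
  250 km from the region centre, headings are nudged back (5 % of the
  bearing error per step). Without it fleets disperse off the grounds within
  the 48 h window and vessels average only 2–3 scene appearances, which
  coarsens detection fractions and biases the median-regression α low at
  short lengths; working a ground is also what longline fleets actually do.
* AIS pings at exponential intervals (mean 8 min) with 1 % of pings opening
  a 1–4 h outage — the vast majority of scene passes are bracketed by
  close pings, and hour-scale outages are the exception, which is the
  reception regime the 10-minute fusion rule expects. Dark vessels
  (default 20 %) never ping.
* Eight 420 km square scenes staggered over 48 h near a 460 km-wide ground,
  giving ~6 appearances per broadcasting vessel.
* Detection is Bernoulli in a linear ramp (20 % at 20 m to 90 % at 60 m,
  plateau 0.91); radar length is lognormal around true length (log-sd 0.2);
  false detections are a uniform Poisson field (2×10⁻⁶ km⁻²); detection
  positions carry 50 m noise.
* Fleet mix: 83 % drifting longlines, 10 % carriers, 7 % other, lognormal
  lengths per class (longlines: median 35 m, log-sd 0.35, clipped 12–120 m).

All randomness flows from one seed through named substreams.

What passing tests show — and don't. On these worlds the matching stage is
near-perfect (precision = recall = 1.0 at the default threshold) and the
end-to-end dark-total recovery lands within a few percent with bootstrap
MAPE ≈ 8 %. Real data are harsher in ways the generator does not emulate:
correlated detection failures (sea state, incidence angle), non-lognormal
length-error tails, MMSI reuse and identity noise, gear beacons (the gear
filter is exercised only on hand-built fixtures), shorelines and ports, and
fleet behaviour that changes between the raster-training data and the
campaign. Matching quality on real scenes will be lower, and the estimator
inherits whatever bias the fitted α carries.

## Problem sizes and defaults used in testing

Unit and property tests run on worlds of 40–120 vessels with 2–3 scenes and
150 px rasters. The recovery harness uses 500 vessels (20 % dark), 8 scenes,
a 300-experiment bootstrap, and seeded worlds; interval coverage is measured
over 50 lightweight observation-model worlds (detection and length noise
only — the stochastic stages the estimator sees) at 60 bootstrap experiments
each. The 1000-pixel raster geometry and the 1296-key bookkeeping are
asserted exactly.

## Known limitations

* The score threshold is a single density; false detections are a scalar
  rate, not an image-quality model.
* No covariates other than length enter detectability (sea state, incidence
  angle, polarization, vessel material are unmodelled).
* One vessel contributes at most its bracketing ping pair per scene; longer
  ping histories are not fused.
* Dark detections are not associated across scenes; the estimate counts
  vessel *instances* in scenes, and converting to unique vessels requires
  knowing revisit behaviour.
* The coarse 5 m parameterization limits length resolution of the recovered
  histogram by construction.
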