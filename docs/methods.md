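# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions in `flightmodes`, in the order the pipeline
runs. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and feature derivation

A deployment is a table of GPS fixes: animal id, UTC timestamp, projected
easting/northing in meters, altitude above sea level, tag-reported speed
(km/h), HDOP/VDOP, and a 2-D/3-D fix flag. The package never operates on
unprojected degrees; coordinates must arrive in a metric CRS. Ground
elevation comes from a constant, a pre-attached column, or a plain-text
ESRI ASCII grid sampled nearest-cell — nearest-cell because interpolating
a ~30 m terrain grid below its native resolution would only smooth noise
into the AGL variable.

Six focal variables describe each fix: tag speed `kph`; step speed `sn`
(horizontal displacement over elapsed time); altitude above ground `agl`;
absolute turn angle `abs_angle`; vertical rate `vr`; and `abs_vr`. The
derived variables are **backward-looking**: the value at fix *i* uses
fixes *i−1* (and *i−2* for the turn angle) of the same animal. A centered
turn-angle convention is equally defensible; the backward convention was
chosen so every derived variable is causal and only the leading fixes of
a segment are incomplete. Derived values are missing when there is no
predecessor, when the interval exceeds the gap threshold (11 s by
default, so all differences are measured over comparable spans), or when
a displacement has zero length (turn undefined). The turn angle is the
change of bearing wrapped to (−π, π], then taken absolute — invariant
under rotation and translation of the coordinate frame.

Duplicate (animal, timestamp) records are collapsed to the first
occurrence at ingestion, because Δt = 0 makes every derived variable
undefined; the collapse is logged.

## Filtering

*First tier* removes fixes whose diagnostics indicate low precision:
HDOP or VDOP **strictly** greater than 10 (a fix at exactly 10.0 is
retained), 2-D fixes, and AGL below −50 m. Optional rule-based caps on
speed and AGL (disabled by default) stand in for the manual outlier
review a human analyst would perform on real data — manual judgment is
not reproducible, a configurable rule is. Each removed fix is attributed
to the first rule it violates, so per-rule counts depend on rule order;
the total retained does not.

*Second tier* drops fixes with any missing focal variable, splits each
animal's remaining sequence wherever consecutive fixes are more than 11 s
apart, and discards runs shorter than 3 fixes. The missing-value drop
runs **before** gap evaluation: removing a fix widens the gap its
neighbours must survive, which is the conservative ordering. Features are
not recomputed after second-tier drops — recomputation would change
Δt-based values across dropped points, and there is no principled
iteration rule for doing so.

## Transform and clustering

Right-skewed variables (`kph`, `sn`, `agl`, `abs_angle`, `abs_vr`) are
square-root transformed; `vr` is signed and roughly symmetric and is left
alone. Negative AGL surviving the first tier (−50 ≤ AGL < 0, i.e. DEM
error near ground level) is clamped to 0 before the square root: a signed
root would manufacture an artificial sub-zero regime out of terrain-model
noise. All six variables are then centered and scaled by their **pooled**
mean and sample (n−1) standard deviation across every retained fix of
every animal; the n−1 choice is immaterial at telemetry scale but is
fixed for reproducibility. The fitted parameters are serialized with the
model so new data can be pushed through the identical transform.

K-means uses Lloyd's algorithm with the classical random-partition
initialization — each start assigns every fix a uniform-random label —
run `n_starts` times (default 10) with the best WSS kept. Convergence is
unchanged labels, capped at 100 iterations; WSS is asserted non-increasing
at every iteration. If a cluster empties during iteration (possible under
random-partition starts), its centroid is re-seeded at the point farthest
from its own centroid, keeping K fixed. Assignment ties break to the
lowest cluster index. All randomness flows from one user seed through
`numpy` `SeedSequence` substreams (one per start, one per candidate K),
so fits are bit-reproducible.

## Choosing K

Three advisory diagnostics, no automatic decision:

1. **Elbow curve** — WSS versus K.
2. **Bootstrapped average silhouette** — the exact silhouette needs the
   full n × n distance matrix, infeasible for millions of fixes, so B
   replicates (default 1000) of n_boot fixes (default 10,000) are drawn
   with replacement and the mean silhouette of each resample is computed
   under the *fixed* full-data labels. The same resample indices are used
   for every candidate K, so candidates are compared on identical draws
   (a paired design that removes resampling variance from the
   comparison). Plain Euclidean distance is used — the standard
   silhouette metric; duplicated rows count as distinct points at
   distance zero; a point in a singleton cluster scores 0 by convention;
   replicates containing fewer than two clusters for some K are recorded
   as missing for that K.
3. **PCA biplot lineup** — eigen-decomposition of the covariance of the
   already-standardized features (equivalently a correlation-scale PCA of
   the raw features), with eigenvector signs normalized so the
   largest-magnitude loading of each component is positive, and scores
   for a seeded subsample exported once per candidate K.

The ranking by mean bootstrapped silhouette is labeled advisory because a
high silhouette can favor a coarse stationary-vs-flight split that hides
biologically distinct flight modes; the final choice belongs to the
analyst looking at the biplots and the scientific question.

## Behavioral interpretation

For K = 4 the fitted centroids, de-standardized to natural units, are
named by a deterministic rule: the centroid slowest by mean rank of the
two speed variables is *perching*; of the rest, the largest vertical rate
is *ascending*, the smallest *gliding*, the remainder *flapping*. Ties
raise an error asking for a manual mapping, and a user-supplied mapping
always overrides the rule — on real data behavior naming is expert
judgment, the rule is a convenience that encodes the canonical raptor
pattern.

Subsegments are maximal same-cluster runs within a segment; a single
point is a legitimate subsegment of duration 0 s. Duration bins default
to {exactly 0 s; (0, 22] s; > 22 s}, half-open on the left so single
points form their own bin; the 22 s boundary is inclusive. Transition
matrices count, for each subsegment, the behavior of its successor — or
a terminal *segment_end* state if it is the last of its segment — and
normalize rows; the diagonal is structurally zero because runs are
maximal. Per-cluster boxplot statistics use linear-interpolation
quantiles and 1.5 × IQR whiskers clipped to the data range, computed on
the original (untransformed) scale. Perching fixes participate in
subsegments and transitions exactly like flight clusters.

## The synthetic-data generator

`simulate_tracks` produces labeled, eagle-like deployments so every stage
of the pipeline is testable without field data. A semi-Markov chain
switches among four regimes — perching, ascending (thermalling),
flapping, gliding — with exponential dwell times (minimum one fix) and an
embedded transition matrix that includes a *terminate* event (the bird
leaves the recorded bout; the simulator inserts a long gap and restarts).
Within a regime, heading evolves by von Mises turning with the regime's
concentration, the horizontal step is speed × Δt, and altitude integrates
vertical rate × Δt with reflection at the ground plus a capped
exponential relaxation toward the regime's typical altitude band. Fix
intervals are drawn from a distribution on 1–11 s centered near 3 s, with
occasional longer gaps; positions, altitudes and tag speed carry Gaussian
noise; quality faults (HDOP/VDOP > 10, 2-D fixes, deep negative-AGL
spikes) are planted at configurable rates. Everything is reproducible
from one seed.

Two structural choices deserve explanation:

* **Landing approaches.** Perching is entered only from gliding in the
  default chain, and a glide visit whose (pre-drawn) successor is
  perching descends steadily (2–5 m/s) to touchdown instead of honoring
  its drawn dwell — an eagle commits to land via a gliding approach.
  Without this, the transition into perch produces a cloud of
  slow-but-descending fixes that belongs to no real behavior and is
  distinct enough to capture a K-means centroid. Because successors are
  pre-drawn, the embedded transition matrix is unaffected. Similarly, any
  glide reaching canopy height (10 m) ends early at its pre-drawn
  successor rather than skimming the ground with reflected, near-zero
  vertical rate. Both mechanisms steer *gliding* dwell times away from
  the configured exponential mean; the other three regimes obey it, and
  the pure dwell contract is additionally verified on a two-regime
  configuration with no terrain interaction.

* **Signal in every feature.** Pooled standardization rescales any focal
  variable with no between-regime signal into a unit-variance nuisance
  axis, regardless of how small its raw noise is. A "well-separated"
  configuration with tight point-mass attributes in only three variables
  is therefore *not* well separated after standardization, and
  random-partition Lloyd reliably converges to cuts along the nuisance
  axes. The noise-free `well_separated_config` used for the
  exact-recovery check consequently separates the regimes in **all six**
  variables — which is also what real flight data do — and hides every
  regime switch behind a gap so boundary fixes are excluded by the
  segment filter. Under that configuration the pipeline recovers the
  planted regimes exactly.

Default numeric values (speeds ~0.4/22/30/65 km/h; vertical rates
0/+2.8/0/−2.5 m/s; altitude bands 2/300/40/100 m; tortuosity rising from
glide to perch; dwell means 100/40/30/30 s) encode the qualitative
flight-mode pattern — perching slowest and lowest, ascending climbing and
tortuous, gliding fastest, straightest and descending — at separations
representative of real raptor telemetry with meter-scale GPS noise. The
regime mix corresponds to an active part of the day (perching ≈ one third
of fixes); deployments dominated by roosting would dilute the in-flight
structure that the classifier is built to resolve, and K-selection
diagnostics on such data favor the coarse perch/flight split for the
reason given above.

## What the synthetic tests do and do not show

The generator reproduces the *structure* the classifier assumes:
regime-specific attribute distributions, irregular short-interval
sampling with gaps, multi-scale subsegment durations, GPS noise, planted
quality faults. It does not emulate terrain interaction, wind and thermal
fields, altitude-dependent behavior within a regime, tag duty-cycling
feedback, or gradual behavioral transitions — on real data the regimes
are not conditionally independent draws, boundaries are softer, and the
true number of behaviors is not known. Passing the recovery tests
therefore demonstrates that the implementation is correct and that the
method can resolve regimes of the assumed structure at realistic noise —
not that four clusters are the right description of any particular
species' flight.

## Numerical choices and degenerate inputs

* Zero-variance features raise an error naming the variable (with a
  relative tolerance, so a column constant up to floating-point rounding
  is caught).
* Rank-deficient PCA inputs are allowed; zero eigenvalues are clipped at
  zero.
* Silhouette of coincident clusters (a = b = 0) is defined as 0.
* An empty resample-cluster replicate is missing, not an error; counts
  are reported.
* Transition-matrix rows with zero total are reported as undefined (NaN)
  rather than renormalized.
* Filters are idempotent; applying either tier to its own output changes
  nothing.
* Problem sizes in the test and acceptance runs (20,000-fix deployments
  for recovery and K-selection, 50,000 for transition estimation, B = 100
  × n_boot = 2,000 silhouette bootstraps) were chosen as the smallest
  sizes at which the sampling error of each measured quantity is well
  inside the margin being asserted.

## Known limitations

* Coordinates must already be projected; no geographic-to-UTM conversion
  is provided.
* DEM support is nearest-cell over ESRI ASCII grids or a constant; no
  GeoTIFF reader and no CRS verification (ASCII grids carry no CRS
  metadata).
* The automatic behavior-naming rule is defined only for K = 4; other K
  get generic cluster names.
* Random-partition initialization (kept for fidelity to the classical
  algorithm description) is weaker than k-means++ on pathological
  geometries; the multi-start mechanism is the only safeguard, so
  `n_starts` should not be reduced below the default.
* The bootstrapped silhouette compares candidate K under labels fit once
  on the full data; it does not propagate clustering uncertainty itself.
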