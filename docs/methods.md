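# Methods

## The fused space-time field

The package assumes the two pollution inputs are complementary: an annual
raster carries spatial variability with no temporal signal, and an hourly
station series carries temporal variability at a single point.  The fused
field shifts the raster's spatial anomaly hour by hour,

    C(p, t) = C_base(t) + ( annual(p) − annual(base) ),

which preserves both marginals exactly: differences between two locations
at the same hour equal the annual-raster differences, and differences
between two hours at the same location equal the station differences.
This additivity is the key testable property and holds everywhere except
where the sum would be negative, in which case the value is clamped to 0
(physical concentrations) and the clamp counted.  An additive adjustment
is one of two common choices; a multiplicative (ratio) adjustment behaves
differently in clean cells during clean hours and is deliberately out of
scope here.

The representative station minimizes the sample variance (n−1
denominator) of its hourly difference series against the raster, among
stations without obvious outliers.  "Obvious outlier" is operationalized
as any hour with |D_t − mean(D)| > z·sd(D), z = 5 by default — a declared
stand-in, config-exposed, since no sharper rule is standard.  A manual
override is retained because variance ranking alone may not capture
siting considerations (e.g. preferring a station in a different land-use
context with a near-minimal variance); the default is the strict minimum
with ties broken by station id.

Hourly station values apply as a step function over [hour, hour+1).
Missing base-station hours are linearly interpolated across gaps of at
most 3 h; longer gaps stay excluded and any exposure computation touching
them fails loudly rather than extrapolating.

## Trip exposure integration

A matched trip is traversed at the constant speed implied between
consecutive fix times.  The space-time path is cut at every grid-cell
boundary crossing and every clock-hour boundary; each piece contributes
C·Δt with C the fused value of its cell and hour.  Cuts are computed
analytically (line-gridline intersections in the lon/lat plane, hour
boundaries in time), so piece durations are exact differences on a common
time grid and telescope to the trip duration to machine precision
(observed ≤ 1e-15 relative).  Exposure is reported both as the raw
integral EI (μg·h/m³) and as the time-weighted average TWA = EI/(λ·
duration) (μg/m³); the TWA is what hourly and daily summaries aggregate,
since it is directly comparable with guideline concentrations.

λ, the in-cabin filtration coefficient, defaults to 1.0 (open windows);
it rescales every EI linearly and leaves every TWA unchanged.  Only
occupied (passenger-carrying) runs count as trips; vacant cruising is not
part of the exposure sum.  Fleet hourly means are time-weighted: each
trip contributes its within-hour time-weighted mean as a sample weighted
by the time spent in that hour; confidence intervals use the normal
approximation (z = 1.959964 for 95%) with reliability-weighted variance,
reducing to the textbook mean ± z·sd/√n for equal weights.  A single
sample yields a degenerate CI equal to the mean.  Daily driver values are
Σ EI / (λ Σ duration) over the driver's trips of that (start-date) day;
fleet daily values are unweighted means over drivers; weekday = Mon–Fri
in local time.

## Map matching

Hidden-Markov matching with Viterbi decoding.  Candidates are nearest
points on edges within 50 m of a fix (projection in degree space,
distances by haversine with R = 6371.0088 km).  Emission log-probability
is −d²/(2σ²) with σ = 10 m; transition log-probability is
−|route − great-circle|/β with β = 200 m, route distances along the
network from a precomputed all-pairs node-distance matrix.  All three
parameters are config-exposed; the defaults are standard magnitudes for
urban GPS.  Ties prefer the candidate on the previous state's edge, then
the lowest edge id, making the decode deterministic.  A fix with no
candidate in range (or unreachable along the network) splits the trip;
each part is matched independently and must still pass the trip filters
(≥2 fixes, ≥60 s, ≥200 m matched distance — declared values, since no
standard exists).  The cleaning step before extraction drops fixes
outside the raster extent, duplicate timestamps (first kept) and fixes
implying >120 km/h from the previous surviving fix, removing the first
violator of a run per pass and iterating to a fixpoint, which makes
cleaning idempotent.

The network is treated as undirected and turn restrictions are ignored;
matching quality therefore degrades on one-way systems, which the
synthetic test bed does not model.

## The synthetic scenario

The generator produces every input the pipeline consumes, plus ground
truth, so recovery can be measured end to end:

* **Annual raster**: constant background 45.5 μg/m³ plus Gaussian bumps
  (two urban hotspots of +30 and +20 μg/m³ by default) on a 0.01° grid
  over a 0.5° × 0.5° extent — a moderate-air-quality city with polluted
  central districts.
* **Stations**: nine sites; hourly value = annual-at-site × diurnal
  multiplier × episode multiplier + N(0, 5²), clipped at 0.  The diurnal
  profile peaks in the night/early morning and morning rush and dips in
  the early afternoon; the episode is a raised-cosine bump shared by all
  stations, scaled so the most polluted station peaks near 300 μg/m³
  (days 3–5 of the default 7-day window) — emulating a multi-day regional
  pollution event.
* **Road network**: an axis-aligned lattice at 0.01° spacing (a radial
  variant is available); edge lengths are geodesic.
* **Taxis**: 50 vehicles for 7 days by default, moving at a constant
  30 km/h along shortest paths to uniformly random destination nodes;
  passenger status flips at exponential times (mean 10 min occupied /
  5 min vacant), independent of routing, so flips can occur mid-edge.
  Fixes are emitted every 10 s as the true position plus isotropic
  Gaussian noise (σ = 10 m).  All randomness derives from per-taxi
  substreams of the scenario seed; identical seeds give byte-identical
  outputs.

Ground truth keeps each taxi's exact piecewise-linear motion, the
traversed edge per instant, and per-trip exposure.  The exposure oracle
integrates the piecewise-constant field *exactly* along the true path
(cutting at cell/hour crossings); a stepped midpoint Riemann mode exists
to demonstrate quadrature convergence (1-s steps agree with the exact
integral to ~1e-5 median, 1e-3 worst-case relative on short trips).  The
oracle shares no code with the pipeline's segmentation: it works on the
generator's true path, not on matched trips.

What the generator does **not** emulate: congestion and speed variation,
demand patterns (origins/destinations are uniform over nodes), one-way
streets, urban-canyon GPS error correlation, station measurement drift,
and raster bias.  Passing recovery tests therefore demonstrates the
correctness of the fusion/matching/integration machinery under the
stated noise model, not the field accuracy of the exposure estimates on
real fleets.

A consequence of desk scale: the study eligibility rule (≥10 distinct
weekdays or ≥4 weekend days of operation) cannot be met inside a 7-day
window, so the rule's thresholds are config fields with the study values
as defaults, and short-scenario configurations scale them to the window
length (the example configs do this explicitly).

## Numerical and design choices

* Geodesy: haversine on a sphere of R = 6371.0088 km everywhere; declared
  constant so tests are exact.  KDE densities and bandwidths are in
  degrees (0.001° cells, 0.005° quartic bandwidth by default); at city
  scale the lon/lat anisotropy (~14% at 30°N) is a documented caveat, not
  corrected.
* Grid convention: cell (r, c) covers the half-open box
  [origin + c·s, origin + (c+1)·s) × [origin + r·s, origin + (r+1)·s),
  rows increasing northward; points exactly on the outer upper boundary
  fold into the outermost cell so that networks drawn to the raster edge
  remain evaluable.
* Variances and SDs use the n−1 denominator throughout.
* Extreme groups: top/bottom ceil(fraction·n) of eligible drivers by mean
  daily TWA, ties by driver id; fraction defaults to 0.01.
* Air-quality categories use half-open bins [0,35), [35,75), [75,115),
  [115,∞) μg/m³; the WHO 24-h reference is 25 μg/m³.
* Rasters are read/written as ESRI ASCII grids or GeoTIFFs; GeoTIFF
  georeferencing is parsed from the ModelPixelScale/ModelTiepoint/GeoKey
  tags directly and only geographic (degree) rasters are accepted.
* File outputs use fixed float formatting and sorted JSON keys; no output
  embeds wall-clock time, so pipeline reruns are byte-identical.

## Problem sizes

The test suite exercises the full default scenario (50 taxis × 7 days,
~3M fixes, ~30k trips) once for the recovery checks (~2–3 min on one
CPU); unit and property tests run on a 2-taxi × 1-day scenario over a
0.2° extent.  `scripts/acceptance.py` reruns the default scenario from
scratch with the given seed.  Observed at that scale: map-matching edge
accuracy ≈ 98% at σ = 10 m (100% of trips exact at σ = 0), median
per-trip TWA recovery error ≈ 0.001%, segmentation time-conservation
error ≤ 1e-15 relative, KDE mass error ≤ 0.1%.

## Known limitations

* Single-station temporal driver: hour-to-hour spatial decorrelation
  between districts is not representable; the additive form can clamp in
  clean cells during clean hours.
* Exposure while vacant (cruising, breaks) is not counted; the daily TWA
  is a working-trip average, not a 24-h personal exposure.
* The HMM has no turn penalties or one-way handling.
* KDE surfaces are descriptive; no significance testing of hotspots.
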